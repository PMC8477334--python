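"""Per-sample repertoire diversity and its clinical associations.

The primary diversity metric is CPK — unique clonotypes per 1000 TCR reads —
chosen for its weak dependence on sequencing depth; Shannon entropy (nats) and
the Gini-Simpson index are computed alongside for comparison. Associations
with the immune metagene score and with sequencing depth use a linear mixed
model with a patient random intercept; the outcome comparison within the
proliferative subtype uses a two-sided Mann-Whitney U test, since repeated
measures are not available for all patients in that subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pmltcr.repertoire_io import CohortRepertoire
from pmltcr.stats_core import TestResult, lmm_association, mann_whitney_u

logger = logging.getLogger(__name__)

__all__ = [
    "compute_diversity",
    "depth_dependence",
    "metagene_score",
    "diversity_module_association",
    "outcome_comparison",
]


def compute_diversity(cohort: CohortRepertoire) -> pd.DataFrame:
    """Per-sample diversity metrics.

    Returns a DataFrame with sample_id, total_reads, unique_clonotypes,
    cpk (unique clonotypes per 1000 reads), shannon (nats) and simpson
    (Gini-Simpson, 1 - sum p^2). Samples with zero reads are excluded with a
    log line.
    """
    totals = cohort.sample_totals
    zero = totals["total_reads"] == 0
    if zero.any():
        logger.info("excluding %d zero-read samples from diversity", int(zero.sum()))
    totals = totals[~zero]

    shannon = {}
    simpson = {}
    for sid, grp in cohort.records.groupby("sample_id"):
        p = grp["read_count"].to_numpy(dtype=float)
        p = p / p.sum()
        shannon[sid] = float(-(p * np.log(p)).sum())
        simpson[sid] = float(1.0 - (p**2).sum())

    out = totals.copy()
    out["cpk"] = out["unique_clonotypes"] / out["total_reads"] * 1000.0
    out["shannon"] = out["sample_id"].map(shannon)
    out["simpson"] = out["sample_id"].map(simpson)
    return out.reset_index(drop=True)


def _patient_map(cohort: CohortRepertoire) -> pd.Series:
    return cohort.samples.set_index("sample_id")["patient_id"]


def depth_dependence(div: pd.DataFrame, metric: str, patient_ids) -> TestResult:
    """Mixed-model association of a diversity metric with total TCR reads.

    Used to rank candidate metrics: a metric strongly associated with depth is
    a poor diversity readout for variable-depth bulk RNA-seq.
    """
    patients = np.asarray(patient_ids)
    if np.unique(patients).size < 2:
        raise ValueError("need at least two patients")
    return lmm_association(div[metric].to_numpy(), div["total_reads"].to_numpy(), patients)


def metagene_score(expression: pd.DataFrame, gene_set) -> pd.Series:
    """Immune metagene score: mean per-gene z-score over the gene set.

    ``expression`` is genes x samples. Genes with zero variance across samples
    are dropped with a log line; an empty intersection raises, naming the
    missing genes.
    """
    genes = [g for g in gene_set if g in expression.index]
    missing = [g for g in gene_set if g not in expression.index]
    if not genes:
        raise ValueError(f"no gene of the set found in the matrix; missing: {missing}")
    if missing:
        logger.info("metagene score: %d gene(s) of the set absent from the matrix", len(missing))
    sub = expression.loc[genes].astype(float)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("metagene score: dropping %d zero-variance gene(s)", int((~keep).sum()))
    if not keep.any():
        return pd.Series(0.0, index=expression.columns, name="module_score")
    sub = sub[keep]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    score = z.mean(axis=0)
    score.name = "module_score"
    return score


def diversity_module_association(cpk, scores, patient_ids) -> TestResult:
    """Mixed-model association of CPK with the immune metagene score
    (cpk ~ score + (1 | patient)). The slope sign is the readout of interest."""
    return lmm_association(np.asarray(cpk, dtype=float), np.asarray(scores, dtype=float), np.asarray(patient_ids))


def outcome_comparison(
    div: pd.DataFrame,
    metadata: pd.DataFrame,
    subtype: str | None = "proliferative",
) -> TestResult:
    """CPK in regressive vs progressive/persistent lesions (Mann-Whitney).

    Restricted to biopsies of the given molecular subtype when ``subtype`` is
    not None. ``extra`` carries group sizes plus both the mean and median CPK
    of each group.
    """
    meta = metadata.set_index("sample_id")
    df = div.join(meta[["sample_type", "subtype", "outcome"]], on="sample_id")
    df = df[df["sample_type"] == "biopsy"]
    if subtype is not None:
        df = df[df["subtype"] == subtype]
    reg = df.loc[df["outcome"] == "regressive", "cpk"].to_numpy()
    prog = df.loc[df["outcome"] == "progressive/persistent", "cpk"].to_numpy()
    if reg.size == 0 or prog.size == 0:
        raise ValueError("both outcome groups must be nonempty after filtering")
    res = mann_whitney_u(reg, prog)
    res.extra.update(
        {
            "n_regressive": int(reg.size),
            "n_progressive": int(prog.size),
            "mean_cpk_regressive": float(reg.mean()),
            "mean_cpk_progressive": float(prog.mean()),
            "median_cpk_regressive": float(np.median(reg)),
            "median_cpk_progressive": float(np.median(prog)),
        }
    )
    return res
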