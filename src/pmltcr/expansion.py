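"""Clonal-expansion calling and recurrence testing.

Clone abundances are normalized to counts per thousand reads (CPT) within each
sample; a clone is called expanded when its CPT exceeds the cohort-wide mean
by more than three standard deviations, where mean and SD pool every
(clonotype, sample) CPT observation across retained samples. Samples with
fewer than 250 total TCR reads are removed first, because low totals inflate
normalized counts. Recurrence of expansion at the same lesion (patient +
location) across timepoints is tested against a permutation null that
shuffles expanded/not-expanded labels across all observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pmltcr.repertoire_io import CohortRepertoire
from pmltcr.stats_core import TestResult, TwoByTwo, correlation, fisher_exact_2x2, permutation_p

logger = logging.getLogger(__name__)

__all__ = [
    "ExpansionThreshold",
    "RecurrenceResult",
    "call_expansions",
    "depth_bias_check",
    "recurrent_expansion_test",
    "expansion_sharing_enrichment",
]


@dataclass(frozen=True)
class ExpansionThreshold:
    """Cohort-wide expansion cutoff: mean CPT + multiplier * SD."""

    mean_cpt: float
    sd_cpt: float
    cutoff: float
    sd_multiplier: float
    n_samples_used: int
    n_samples_filtered: int


@dataclass
class RecurrenceResult:
    """Observed recurrent-expansion count and its permutation p-value."""

    observed: int
    p_value: float
    n_permutations: int
    recurrent: pd.DataFrame  # (patient_id, location, chain?, cdr3_aa) triples


def call_expansions(
    cohort: CohortRepertoire,
    min_reads: int = 250,
    sd_multiplier: float = 3.0,
    per_clonotype: bool = False,
) -> tuple[ExpansionThreshold, pd.DataFrame]:
    """Call expanded clones across retained biopsy samples.

    Parameters
    ----------
    cohort
        Cohort to analyze; only biopsy samples are considered.
    min_reads
        Minimum total TCR reads for a sample to enter the analysis.
    sd_multiplier
        Number of SDs above the mean defining the cutoff.
    per_clonotype
        When True, the mean/SD is computed per clonotype across samples
        instead of pooled over all observations (sensitivity-analysis
        variant; clonotypes observed once fall back to the pooled cutoff).

    Returns
    -------
    (threshold, calls)
        ``calls`` has one row per (sample, clonotype) of the retained samples
        with columns sample_id, chain, cdr3_aa, cpt, expanded.
    """
    biopsies = cohort.subset_type("biopsy")
    totals = biopsies.sample_totals.set_index("sample_id")["total_reads"]
    retained = totals[totals >= min_reads].index
    n_filtered = int((totals < min_reads).sum())
    if len(retained) == 0:
        raise ValueError(f"no sample has >= {min_reads} total reads")
    logger.info("read filter (>= %d): retained %d samples, removed %d", min_reads, len(retained), n_filtered)

    rec = biopsies.records[biopsies.records["sample_id"].isin(retained)].copy()
    rec["cpt"] = rec["read_count"] / rec["sample_id"].map(totals) * 1000.0

    pooled_mean = float(rec["cpt"].mean())
    pooled_sd = float(rec["cpt"].std(ddof=1)) if len(rec) > 1 else 0.0
    cutoff = pooled_mean + sd_multiplier * pooled_sd

    if per_clonotype:
        key_cols = biopsies.key_columns
        g = rec.groupby(key_cols)["cpt"]
        mu = g.transform("mean")
        sd = g.transform("std").fillna(0.0)
        n = g.transform("size")
        per_cut = mu + sd_multiplier * sd
        rec["expanded"] = np.where(n > 1, rec["cpt"] > per_cut, rec["cpt"] > cutoff)
    else:
        rec["expanded"] = rec["cpt"] > cutoff

    threshold = ExpansionThreshold(
        mean_cpt=pooled_mean,
        sd_cpt=pooled_sd,
        cutoff=cutoff,
        sd_multiplier=sd_multiplier,
        n_samples_used=int(len(retained)),
        n_samples_filtered=n_filtered,
    )
    cols = ["sample_id", "chain", "cdr3_aa", "cpt", "expanded"]
    return threshold, rec[cols].reset_index(drop=True)


def depth_bias_check(calls: pd.DataFrame, totals: pd.DataFrame) -> TestResult:
    """Pearson correlation of per-sample expanded-clone count with depth.

    A non-significant correlation (p > 0.05) indicates the read filter removed
    the depth artifact; the verdict is in ``extra["depth_independent"]``.
    """
    counts = calls.groupby("sample_id")["expanded"].sum()
    t = totals.set_index("sample_id")["total_reads"].reindex(counts.index)
    if counts.size < 3:
        raise ValueError("need at least three retained samples")
    if counts.nunique() == 1:
        res = TestResult(statistic=0.0, p_value=1.0, estimate=0.0, method="pearson_degenerate")
    else:
        res = correlation(counts.to_numpy(dtype=float), t.to_numpy(dtype=float), method="pearson")
    res.extra["depth_independent"] = bool(res.p_value > 0.05)
    return res


def _recurrence_count(group_ids: np.ndarray, labels: np.ndarray, n_groups: int) -> int:
    # groups = (patient, location, clonotype); count groups with expanded
    # observations at >= 2 (necessarily distinct) timepoints
    counts = np.bincount(group_ids[labels], minlength=n_groups)
    return int(np.sum(counts >= 2))


def recurrent_expansion_test(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 17,
) -> RecurrenceResult:
    """Permutation test for recurrent expansion at the same lesion.

    The observed statistic counts distinct (patient, location, clonotype)
    triples expanded at two or more timepoints. The null shuffles the
    expanded/not-expanded labels uniformly across all (clonotype, sample)
    observations of the retained samples, preserving the total number of
    expanded labels in every draw.
    """
    meta = metadata.set_index("sample_id")
    df = calls.join(meta[["patient_id", "location", "timepoint"]], on="sample_id")
    key_cols = ["patient_id", "location", "chain", "cdr3_aa"]
    group_ids, uniques = pd.factorize(pd.MultiIndex.from_frame(df[key_cols]))
    labels = df["expanded"].to_numpy(dtype=bool)
    n_groups = len(uniques)

    observed = _recurrence_count(group_ids, labels, n_groups)
    recurrent_keys = np.bincount(group_ids[labels], minlength=n_groups) >= 2
    recurrent = pd.DataFrame(
        [uniques[i] for i in np.flatnonzero(recurrent_keys)], columns=key_cols
    )

    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    perm = labels.copy()
    for b in range(n_perm):
        rng.shuffle(perm)
        draws[b] = _recurrence_count(group_ids, perm, n_groups)
    p = permutation_p(observed, draws, tail="ge")
    return RecurrenceResult(observed=observed, p_value=p, n_permutations=n_perm, recurrent=recurrent)


def expansion_sharing_enrichment(calls: pd.DataFrame, cohort: CohortRepertoire) -> TestResult:
    """Are within-patient shared clonotypes more often expanded?

    Clonotypes are split into those found in a single biopsy and those found
    in two or more biopsies of the same patient; the 2x2 against
    expanded-in-at-least-one-retained-sample is tested by Fisher's exact test.
    Clonotypes shared only across patients belong to neither category and are
    excluded.
    """
    biopsies = cohort.subset_type("biopsy")
    key_cols = biopsies.key_columns
    rec = biopsies.records.merge(
        biopsies.samples[["sample_id", "patient_id"]], on="sample_id", how="left"
    )
    per_key = rec.groupby(key_cols).agg(
        n_samples=("sample_id", "nunique"),
    )
    per_patient_max = (
        rec.groupby(key_cols + ["patient_id"])["sample_id"].nunique().groupby(key_cols).max()
    )
    per_key["max_within_patient"] = per_patient_max

    expanded_keys = set(
        map(tuple, calls.loc[calls["expanded"], key_cols].itertuples(index=False, name=None))
    )
    single = per_key[per_key["n_samples"] == 1]
    multi = per_key[per_key["max_within_patient"] >= 2]
    if single.empty or multi.empty:
        raise ValueError("both the single-sample and multi-sample-within-patient categories must be nonempty")

    def n_exp(index) -> int:
        return sum(1 for k in index if tuple(k) in expanded_keys)

    e_multi, e_single = n_exp(multi.index), n_exp(single.index)
    t = TwoByTwo(e_multi, len(multi) - e_multi, e_single, len(single) - e_single)
    res = fisher_exact_2x2(t)
    res.extra.update(
        {
            "pct_expanded_multi_within_patient": e_multi / len(multi) * 100.0,
            "pct_expanded_single_sample": e_single / len(single) * 100.0,
            "n_multi": int(len(multi)),
            "n_single": int(len(single)),
        }
    )
    return res
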