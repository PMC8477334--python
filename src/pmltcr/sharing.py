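"""All-pairs clone-sharing enrichment between biopsies.

For every unordered pair of biopsies, a 2x2 table compares the clonotypes
shared and unique to each sample against the background of the full cohort
clonotype universe (biopsies and brushes when brushes are loaded). Fisher's
exact test identifies enriched pairs; BH-FDR is applied jointly across all
pairs; pairs are grouped by whether they share patient, anatomic location, and
procedure timepoint, and the groups' log2 odds ratios are compared by one-way
ANOVA with Tukey HSD.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from pmltcr.repertoire_io import CohortRepertoire
from pmltcr.stats_core import TwoByTwo, anova_tukey, bh_fdr, fisher_exact_2x2, haldane_odds_ratio

logger = logging.getLogger(__name__)

GROUPS = (
    "different_patient",
    "same_patient_only",
    "same_patient_same_location",
    "same_patient_same_time",
)

__all__ = ["pair_table", "pairwise_enrichment", "group_summary", "compare_groups", "GROUPS"]


def pair_table(keys_a, keys_b, universe_size: int) -> TwoByTwo:
    """2x2 sharing table for two repertoires against a clonotype universe.

    Cells: a = shared, b = unique to A, c = unique to B, d = universe members
    in neither sample.
    """
    sa, sb = set(keys_a), set(keys_b)
    union = len(sa | sb)
    if universe_size < union:
        raise ValueError(f"universe size {universe_size} smaller than the union of the pair ({union})")
    shared = len(sa & sb)
    a_only = len(sa) - shared
    b_only = len(sb) - shared
    return TwoByTwo(shared, a_only, b_only, universe_size - shared - a_only - b_only)


def _group_label(meta_a, meta_b) -> str:
    if meta_a.patient_id != meta_b.patient_id:
        return "different_patient"
    same_time = meta_a.timepoint == meta_b.timepoint
    same_loc = meta_a.location == meta_b.location
    if same_time:
        return "same_patient_same_time"
    if same_loc:
        return "same_patient_same_location"
    return "same_patient_only"


def pairwise_enrichment(
    cohort: CohortRepertoire,
    sample_type: str = "biopsy",
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Sharing enrichment for every unordered pair of biopsies.

    The background universe is the full cohort's clonotype set (including
    brushes when present); samples with empty repertoires are excluded with a
    log line. Returns one row per pair with the 2x2 cells, Haldane odds ratio,
    log2 OR, Fisher p, BH-FDR across all pairs, the enriched flag
    (fdr < threshold and OR > 1), and the patient/location/time group label.
    """
    universe_size = len(cohort.universe)
    logger.info("sharing universe: %d clonotypes", universe_size)
    meta = cohort.samples[cohort.samples["sample_type"] == sample_type]
    keys = {sid: cohort.sample_keys(sid) for sid in meta["sample_id"]}
    empty = [sid for sid, k in keys.items() if not k]
    if empty:
        logger.info("excluding %d empty-repertoire samples from pairing", len(empty))
    meta = meta[~meta["sample_id"].isin(empty)]
    if len(meta) < 2:
        raise ValueError("need at least two non-empty samples to form pairs")

    meta_by_id = {m.sample_id: m for m in meta.itertuples(index=False)}
    rows = []
    for sid_a, sid_b in itertools.combinations(sorted(meta_by_id), 2):
        t = pair_table(keys[sid_a], keys[sid_b], universe_size)
        res = fisher_exact_2x2(t)
        or_est = haldane_odds_ratio(t)
        rows.append(
            {
                "sample_a": sid_a,
                "sample_b": sid_b,
                "shared": t.a,
                "a_only": t.b,
                "b_only": t.c,
                "neither": t.d,
                "or_estimate": or_est,
                "log2_or": float(np.log2(or_est)),
                "p": res.p_value,
                "group": _group_label(meta_by_id[sid_a], meta_by_id[sid_b]),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["enriched"] = (df["fdr"] < fdr_threshold) & (df["or_estimate"] > 1)
    logger.info("tested %d pairs; %d enriched at FDR<%g", len(df), int(df["enriched"].sum()), fdr_threshold)
    return df


def group_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-group pair counts, percent enriched, and mean (log2) odds ratios.

    Groups with zero pairs are omitted with a log line.
    """
    if results.empty:
        raise ValueError("no pair results to summarize")
    rows = []
    for group in GROUPS:
        sub = results[results["group"] == group]
        if sub.empty:
            logger.info("group %s has zero pairs; omitted from summary", group)
            continue
        n_enriched = int(sub["enriched"].sum())
        n_non = len(sub) - n_enriched
        rows.append(
            {
                "group": group,
                "non_enriched_pairs": n_non,
                "enriched_pairs": n_enriched,
                "percent_enriched": percent_enriched(n_non, n_enriched),
                "mean_or": float(sub["or_estimate"].mean()),
                "mean_log2_or": float(sub["log2_or"].mean()),
            }
        )
    return pd.DataFrame(rows)


def percent_enriched(non_enriched: int, enriched: int) -> float:
    """Percentage of pairs enriched: enriched / (enriched + non_enriched) * 100."""
    total = enriched + non_enriched
    if total == 0:
        raise ValueError("no pairs")
    return enriched / total * 100.0


def compare_groups(results: pd.DataFrame):
    """ANOVA + Tukey HSD on per-pair log2 odds ratios across sharing groups.

    Returns (anova TestResult, {(group_i, group_j): TestResult}).
    """
    groups = {
        g: sub["log2_or"].to_numpy()
        for g, sub in results.groupby("group")
        if len(sub) >= 2
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups with two or more pairs")
    return anova_tukey(groups)
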