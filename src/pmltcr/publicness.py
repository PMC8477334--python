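"""Public/private clonotype classification and antigen-database annotation.

A clonotype is public when it is found in more than one patient of the cohort
(biopsies and brushes both count, which sharpens the patient tally) or, for
beta-chain sequences, when it also appears in a large external healthy-donor
CDR3 list. Public and private clonotypes are then matched exactly against
antigen-specificity database tables (McPAS-TCR-like CSV, VDJdb-like TSV) and
the enrichment of database hits among public clones — and of public clones
among expansions — is tested with Fisher's exact test.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from pmltcr.repertoire_io import CohortRepertoire
from pmltcr.stats_core import TestResult, TwoByTwo, fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "classify_public",
    "annotate_databases",
    "db_enrichment_public_vs_private",
    "public_among_expanded",
    "sensitivity_without_public",
]

MCPAS_COLUMNS = {"beta": "CDR3.beta.aa", "alpha": "CDR3.alpha.aa",
                 "pathology": "Pathology", "antigen": "Antigen.protein"}
VDJDB_COLUMNS = {"cdr3": "cdr3", "gene": "gene",
                 "epitope": "antigen.epitope", "species": "antigen.species"}


def classify_public(cohort: CohortRepertoire, reference_beta: Iterable[str] = ()) -> pd.DataFrame:
    """Classify every clonotype of the cohort as public or private.

    Returns a DataFrame indexed by clonotype with columns chain, cdr3_aa,
    n_patients, in_reference, public. The external reference applies to
    beta-chain sequences only.
    """
    ref = set(reference_beta)
    rec = cohort.records.merge(cohort.samples[["sample_id", "patient_id"]], on="sample_id", how="left")
    key_cols = cohort.key_columns
    ann = rec.groupby(key_cols).agg(n_patients=("patient_id", "nunique")).reset_index()
    if "chain" not in ann.columns:  # pooled-chain cohorts carry no chain in the key
        chain_of = rec.groupby("cdr3_aa")["chain"].first()
        ann["chain"] = ann["cdr3_aa"].map(chain_of)
    ann["in_reference"] = ann["cdr3_aa"].isin(ref)
    ann["public"] = (ann["n_patients"] >= 2) | ((ann["chain"] == "TRB") & ann["in_reference"])
    return ann[["chain", "cdr3_aa", "n_patients", "in_reference", "public"]]


def _match_mcpas(mcpas: pd.DataFrame, cols: dict) -> pd.DataFrame:
    rows = []
    n_bad = 0
    for row in mcpas.itertuples(index=False):
        rd = dict(zip(mcpas.columns, row))
        beta_seq = rd.get(cols["beta"])
        alpha_seq = rd.get(cols["alpha"])
        seq, chain = (beta_seq, "TRB") if isinstance(beta_seq, str) and beta_seq else (alpha_seq, "TRA")
        if not isinstance(seq, str) or not seq:
            n_bad += 1
            continue
        rows.append({"cdr3_aa": seq, "db_chain": chain, "database": "mcpas",
                     "antigen": rd.get(cols["antigen"]), "species": rd.get(cols["pathology"])})
    if n_bad:
        logger.info("skipped %d malformed McPAS-like rows", n_bad)
    return pd.DataFrame(rows, columns=["cdr3_aa", "db_chain", "database", "antigen", "species"])


def _match_vdjdb(vdjdb: pd.DataFrame, cols: dict) -> pd.DataFrame:
    rows = []
    n_bad = 0
    for row in vdjdb.itertuples(index=False):
        rd = dict(zip(vdjdb.columns, row))
        seq = rd.get(cols["cdr3"])
        if not isinstance(seq, str) or not seq:
            n_bad += 1
            continue
        gene = rd.get(cols["gene"])
        rows.append({"cdr3_aa": seq, "db_chain": gene if gene in ("TRA", "TRB", "TRG", "TRD") else None,
                     "database": "vdjdb", "antigen": rd.get(cols["epitope"]), "species": rd.get(cols["species"])})
    if n_bad:
        logger.info("skipped %d malformed VDJdb-like rows", n_bad)
    return pd.DataFrame(rows, columns=["cdr3_aa", "db_chain", "database", "antigen", "species"])


def annotate_databases(
    annotations: pd.DataFrame,
    mcpas: pd.DataFrame | None = None,
    vdjdb: pd.DataFrame | None = None,
    mcpas_columns: dict | None = None,
    vdjdb_columns: dict | None = None,
) -> pd.DataFrame:
    """Attach antigen-database hits to clonotype annotations.

    Matching is exact on the CDR3 amino-acid sequence, chain-aware when the
    database row declares a chain and chain-agnostic otherwise. Adds columns
    n_db_hits, any_db_hit and db_hits (list of (database, antigen, species)
    tuples); multiple hits are all retained.
    """
    frames = []
    if mcpas is not None and not mcpas.empty:
        frames.append(_match_mcpas(mcpas, {**MCPAS_COLUMNS, **(mcpas_columns or {})}))
    if vdjdb is not None and not vdjdb.empty:
        frames.append(_match_vdjdb(vdjdb, {**VDJDB_COLUMNS, **(vdjdb_columns or {})}))
    out = annotations.copy()
    if not frames:
        out["db_hits"] = [[] for _ in range(len(out))]
        out["n_db_hits"] = 0
        out["any_db_hit"] = False
        return out
    db = pd.concat(frames, ignore_index=True)

    by_seq: dict[str, list] = {}
    for row in db.itertuples(index=False):
        by_seq.setdefault(row.cdr3_aa, []).append(row)

    hits_col = []
    for row in out.itertuples(index=False):
        hits = []
        for h in by_seq.get(row.cdr3_aa, []):
            if h.db_chain is None or h.db_chain == row.chain:
                hits.append((h.database, h.antigen, h.species))
        hits_col.append(hits)
    out["db_hits"] = hits_col
    out["n_db_hits"] = [len(h) for h in hits_col]
    out["any_db_hit"] = out["n_db_hits"] > 0
    return out


def db_enrichment_public_vs_private(annotations: pd.DataFrame) -> TestResult:
    """Fisher test of database hits among public vs private clonotypes."""
    pub = annotations[annotations["public"]]
    priv = annotations[~annotations["public"]]
    if pub.empty or priv.empty:
        raise ValueError("both the public and private classes must be nonempty")
    if "any_db_hit" not in annotations.columns or annotations["n_db_hits"].sum() == 0:
        raise ValueError("no database hits to test; run annotate_databases with nonempty tables")
    a = int(pub["any_db_hit"].sum())
    c = int(priv["any_db_hit"].sum())
    t = TwoByTwo(a, len(pub) - a, c, len(priv) - c)
    res = fisher_exact_2x2(t)
    res.extra.update(
        {
            "pct_hits_public": a / len(pub) * 100.0,
            "pct_hits_private": c / len(priv) * 100.0,
            "n_public": int(len(pub)),
            "n_private": int(len(priv)),
        }
    )
    return res


def public_among_expanded(
    annotations: pd.DataFrame,
    calls: pd.DataFrame,
    cohort: CohortRepertoire,
    recurrent: pd.DataFrame | None = None,
) -> TestResult:
    """Fisher test of publicness among expanded vs non-expanded clonotypes.

    The primary comparison set is the clonotypes observed in biopsies; the
    same table over all cohort clonotypes (biopsies + brushes) is reported in
    ``extra['all_samples']``. When ``recurrent`` triples are given, the public
    fraction among recurrently expanded clonotypes is reported too.
    """
    if not calls["expanded"].any():
        raise ValueError("need at least one expanded clone")
    key_cols = cohort.key_columns
    expanded_keys = set(map(tuple, calls.loc[calls["expanded"], key_cols].itertuples(index=False, name=None)))

    ann = annotations.copy()
    ann["_key"] = list(map(tuple, ann[key_cols].itertuples(index=False, name=None)))
    ann["expanded"] = ann["_key"].isin(expanded_keys)

    biopsy_keys = set(cohort.iter_keys(cohort.subset_type("biopsy").records))

    def table(sub: pd.DataFrame) -> tuple[TwoByTwo, dict]:
        e_pub = int((sub["expanded"] & sub["public"]).sum())
        e_priv = int((sub["expanded"] & ~sub["public"]).sum())
        ne_pub = int((~sub["expanded"] & sub["public"]).sum())
        ne_priv = int((~sub["expanded"] & ~sub["public"]).sum())
        extra = {
            "pct_public_expanded": 100.0 * e_pub / max(1, e_pub + e_priv),
            "pct_public_not_expanded": 100.0 * ne_pub / max(1, ne_pub + ne_priv),
        }
        return TwoByTwo(e_pub, e_priv, ne_pub, ne_priv), extra

    sub_biopsy = ann[ann["_key"].isin(biopsy_keys)]
    degenerate = sub_biopsy["public"].all() or (~sub_biopsy["public"]).all()
    t, extra = table(sub_biopsy)
    res = fisher_exact_2x2(t)
    res.extra.update(extra)
    res.extra["degenerate_public_classes"] = bool(degenerate)

    t_all, extra_all = table(ann)
    res_all = fisher_exact_2x2(t_all)
    res.extra["all_samples"] = {"or": res_all.estimate, "p": res_all.p_value, **extra_all}

    if recurrent is not None and not recurrent.empty:
        rec_keys = set(map(tuple, recurrent[key_cols].drop_duplicates().itertuples(index=False, name=None)))
        n_pub = sum(1 for k in rec_keys if k in set(ann.loc[ann["public"], "_key"]))
        res.extra["recurrent_public_fraction"] = n_pub / len(rec_keys)
        res.extra["n_recurrent"] = len(rec_keys)
    return res


def sensitivity_without_public(
    cohort: CohortRepertoire,
    annotations: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    fdr_threshold: float = 0.01,
    subtype: str | None = "proliferative",
) -> dict:
    """Re-run the sharing, diversity-association, and outcome analyses on the
    private-only cohort and report both runs side by side.

    Returns a dict with entries ``full`` and ``private_only``, each holding
    the sharing ANOVA, group summary, the CPK-module association (when scores
    are given) and the outcome comparison; stages that cannot run on the
    reduced cohort are recorded as errors rather than raised.
    """
    from pmltcr.diversity import compute_diversity, diversity_module_association, outcome_comparison
    from pmltcr.sharing import compare_groups, group_summary, pairwise_enrichment

    key_cols = cohort.key_columns
    public_keys = set(map(tuple, annotations.loc[annotations["public"], key_cols].itertuples(index=False, name=None)))

    def run(c: CohortRepertoire) -> dict:
        out: dict = {}
        try:
            pairs = pairwise_enrichment(c, fdr_threshold=fdr_threshold)
            anova, tukey = compare_groups(pairs)
            out["sharing_anova_p"] = anova.p_value
            out["group_summary"] = group_summary(pairs)
        except ValueError as exc:
            out["sharing_error"] = str(exc)
        try:
            div = compute_diversity(c.subset_type("biopsy"))
            meta = c.samples.set_index("sample_id")
            div = div.join(meta[["patient_id"]], on="sample_id")
            if scores is not None:
                merged = div.merge(scores, on="sample_id")
                assoc = diversity_module_association(
                    merged["cpk"], merged["module_score"], merged["patient_id"]
                )
                out["module_assoc_slope"] = assoc.estimate
                out["module_assoc_p"] = assoc.p_value
            oc = outcome_comparison(div, c.samples, subtype=subtype)
            out["outcome_p"] = oc.p_value
            out["outcome_mean_cpk_regressive"] = oc.extra["mean_cpk_regressive"]
            out["outcome_mean_cpk_progressive"] = oc.extra["mean_cpk_progressive"]
        except ValueError as exc:
            out["diversity_error"] = str(exc)
        return out

    report = {"full": run(cohort)}
    private_cohort = cohort.drop_clonotypes(public_keys)
    if private_cohort.records.empty:
        report["private_only"] = {"error": "no private clonotypes remain"}
    else:
        report["private_only"] = run(private_cohort)
    return report
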