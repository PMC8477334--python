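"""Synthetic cohort generator with ground-truth labels.

Emulates a longitudinal bronchoscopy screening cohort: ~50 patients sampled at
yearly procedures, several anatomic locations per patient, endobronchial
biopsies plus mainstem-bronchus brushes, and highly variable per-sample TCR
read depth. Clonotypes are drawn from a shared "public" pool and
patient-private pools, with multiplicative weights that make a patient re-use
clones seen before — strongest for clones seen at the same procedure
timepoint, then the same anatomic location — reproducing the observed ordering
of repertoire sharing. A configurable number of clones is planted as clonally
expanded (some recurring at the same location at the next timepoint), and
regressive lesions draw from an effectively smaller clone pool so their
clonotype diversity (CPK) is reduced by construction. A per-sample immune
metagene score is emitted with a built-in negative coupling to realized CPK.

Every random choice flows from a single seed, so a configuration generates a
byte-identical cohort on every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pmltcr.repertoire_io import ClonotypeRecord, CohortRepertoire, SampleMetadata, build_cohort

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_reference_set",
    "generate_annotation_db",
    "generate_expression",
    "scaled_config",
    "null_config",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# antigen annotations used by the database generator; dominated by common
# viral pathogens, mirroring the composition of real specificity databases
_ANTIGENS = [
    ("Influenza", "M1"),
    ("Influenza", "NP"),
    ("CMV", "pp65"),
    ("CMV", "IE1"),
    ("EBV", "BMLF1"),
    ("EBV", "BRLF1"),
    ("YellowFever", "NS4B"),
    ("HCV", "NS3"),
    ("HIV-1", "Gag"),
    ("MelanomaAssociated", "MART-1"),
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the screening-cohort structure: 50 patients, 3 procedures
    ~1 year apart, 2 biopsied lesions (locations) per patient plus one brush
    per procedure, and a log-normal TCR read-depth distribution under which
    roughly a quarter of biopsies clear the 250-read expansion filter.
    """

    n_patients: int = 50
    timepoints_per_patient: int = 3
    locations_per_patient: int = 2
    brushes_per_patient: int = 3

    # log-normal read depth (natural-log scale): median ~130 reads,
    # P(depth >= 250) ~ 0.26
    depth_log_mean: float = 4.87
    depth_log_sd: float = 1.0

    public_pool_size: int = 800
    private_pool_size: int = 400
    p_public_draw: float = 0.2

    # sharing structure: previously used clones of the same patient are
    # favored on re-draw; extra weight when the earlier use was at the same
    # procedure (time) or the same anatomic location
    within_patient_overlap_boost: float = 3.0
    same_time_boost: float = 2.5
    same_location_boost: float = 1.6

    n_planted_expanded: int = 60
    expansion_fold: float = 50.0
    p_recurrent_expansion: float = 0.6
    # which clone a planted expansion lands on: multiplicative preference for
    # clones the patient used before and for public-pool clones, mirroring
    # the enrichment of expansion among shared and public TCRs
    expanded_reuse_weight: float = 8.0
    public_expansion_weight: float = 3.0

    # fraction of reads that are unique clonotypes scales with depth^exponent;
    # regressive lesions get the fraction multiplied by outcome_effect < 1
    unique_rate: float = 0.55
    unique_exponent: float = 0.85
    outcome_effect: float = 0.6
    p_proliferative: float = 0.5
    p_regressive: float = 0.5

    dirichlet_concentration: float = 8.0
    beta_chain_fraction: float = 0.75

    module_score_slope: float = 1.0
    module_score_noise_sd: float = 0.5

    db_hit_rate_public: float = 0.087
    db_hit_rate_private: float = 0.015

    min_sample_reads: int = 250  # depth threshold targeted when planting expansions
    seed: int = 17

    def validate(self) -> None:
        probs = {
            "p_public_draw": self.p_public_draw,
            "p_recurrent_expansion": self.p_recurrent_expansion,
            "p_proliferative": self.p_proliferative,
            "p_regressive": self.p_regressive,
            "db_hit_rate_public": self.db_hit_rate_public,
            "db_hit_rate_private": self.db_hit_rate_private,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("within_patient_overlap_boost", "same_time_boost", "same_location_boost",
                     "expanded_reuse_weight", "public_expansion_weight"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_patients", "timepoints_per_patient", "locations_per_patient",
                     "public_pool_size", "private_pool_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.expansion_fold < 1.0:
            raise ValueError("expansion_fold must be >= 1")
        if self.n_planted_expanded > self.public_pool_size + self.private_pool_size:
            raise ValueError("planted expansions exceed the per-patient clone pool")


def scaled_config(seed: int = 17, **overrides) -> SyntheticConfig:
    """Reduced cohort (12 patients) with the default effect structure.

    Used for multi-seed replicate suites where the full 50-patient cohort
    would be needlessly slow; all effect parameters match the defaults.
    """
    kwargs = dict(
        n_patients=12,
        public_pool_size=400,
        private_pool_size=300,
        n_planted_expanded=20,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def null_config(seed: int = 17, **overrides) -> SyntheticConfig:
    """Cohort with every planted effect disabled, for type-I calibration.

    Sharing boosts are 1 (no within-patient re-use preference), every sample
    draws from one shared pool (p_public_draw = 1) so patient identity
    carries no information, the outcome has no effect on diversity, and
    planted expansions never recur (p_recurrent_expansion = 0). Expansions
    are still planted — at random positions — so the expansion caller and the
    recurrence permutation statistic stay non-degenerate; their placement
    carries no signal. The pool is small and depth high so repertoires
    overlap enough for the recurrence count to have resolution, and every
    lesion is labelled proliferative so the outcome comparison always has two
    groups.
    """
    kwargs = dict(
        n_patients=6,
        timepoints_per_patient=3,
        locations_per_patient=2,
        brushes_per_patient=0,
        depth_log_mean=6.2,
        depth_log_sd=0.5,
        public_pool_size=400,
        private_pool_size=150,
        p_public_draw=1.0,
        within_patient_overlap_boost=1.0,
        same_time_boost=1.0,
        same_location_boost=1.0,
        n_planted_expanded=100,
        p_recurrent_expansion=0.0,
        expanded_reuse_weight=1.0,
        public_expansion_weight=1.0,
        outcome_effect=1.0,
        p_proliferative=1.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@dataclass
class GroundTruth:
    """Planted labels of a synthetic cohort.

    ``clonotypes`` — per clonotype: chain, cdr3_aa, public flag, origin
    (patient id or "public").
    ``expansions`` — per (sample, clonotype) planted-expanded observation.
    ``samples`` — per sample: true outcome and true module score.
    ``recurrent`` — per (patient, location, clonotype) planted recurrent
    expansion across consecutive timepoints.
    """

    clonotypes: pd.DataFrame
    expansions: pd.DataFrame
    samples: pd.DataFrame
    recurrent: pd.DataFrame


def _random_cdr3(rng: np.random.Generator, taken: set, n: int) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(8, 21))
        s = "C" + "".join(rng.choice(_AA, size=length - 2)) + "F"
        if s not in taken:
            taken.add(s)
            out.append(s)
    return out


def _make_pools(cfg: SyntheticConfig, rng: np.random.Generator):
    """Public pool + per-patient private pools; each clone has a fixed chain."""
    taken: set[str] = set()
    public_seqs = _random_cdr3(rng, taken, cfg.public_pool_size)
    public_chain = np.where(rng.random(cfg.public_pool_size) < cfg.beta_chain_fraction, "TRB", "TRA")
    public = list(zip(public_chain.tolist(), public_seqs))
    private: dict[str, list[tuple[str, str]]] = {}
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        seqs = _random_cdr3(rng, taken, cfg.private_pool_size)
        chains = np.where(rng.random(cfg.private_pool_size) < cfg.beta_chain_fraction, "TRB", "TRA")
        private[pid] = list(zip(chains.tolist(), seqs))
    return public, private


def generate_cohort(config: SyntheticConfig) -> tuple[CohortRepertoire, GroundTruth, pd.DataFrame]:
    """Generate a cohort, its ground truth, and per-sample module scores.

    Returns
    -------
    (cohort, truth, scores)
        ``scores`` is a DataFrame with columns sample_id, module_score
        (biopsies only, mirroring the gene-expression data available for
        lesions).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    public, private = _make_pools(config, rng)
    patients = sorted(private)

    # lesion-level clinical truth: subtype and outcome per (patient, location)
    lesion_info: dict[tuple[str, str], tuple[str, str]] = {}
    for pid in patients:
        for li in range(config.locations_per_patient):
            loc = f"L{li + 1}"
            subtype = "proliferative" if rng.random() < config.p_proliferative else "other"
            outcome = "regressive" if rng.random() < config.p_regressive else "progressive/persistent"
            lesion_info[(pid, loc)] = (subtype, outcome)

    # plan all samples up front so depths are known before planting expansions
    plan = []  # (sample_id, pid, loc, tp, sample_type, depth)
    for pid in patients:
        for tp in range(1, config.timepoints_per_patient + 1):
            for li in range(config.locations_per_patient):
                loc = f"L{li + 1}"
                depth = max(2, int(round(float(rng.lognormal(config.depth_log_mean, config.depth_log_sd)))))
                plan.append((f"{pid}_T{tp}_{loc}", pid, loc, tp, "biopsy", depth))
        n_brush = min(config.brushes_per_patient, config.timepoints_per_patient)
        for tp in range(1, n_brush + 1):
            depth = max(2, int(round(float(rng.lognormal(config.depth_log_mean, config.depth_log_sd)))))
            plan.append((f"{pid}_T{tp}_BR", pid, "BR", tp, "brush", depth))

    # assign expansion slots to biopsies deep enough to survive the read
    # filter; the expanded clone itself is chosen at generation time so it
    # can prefer clones the patient has already used (expanded clones are
    # enriched among within-patient shared clones, as in real repertoires)
    eligible = [p for p in plan if p[4] == "biopsy" and p[5] >= config.min_sample_reads]
    planted_slots: dict[str, int] = {s[0]: 0 for s in plan}
    forced: dict[str, list[tuple[str, str]]] = {s[0]: [] for s in plan}
    recurrent_rows: list[dict] = []
    if eligible and config.n_planted_expanded > 0:
        idx = rng.choice(len(eligible), size=config.n_planted_expanded, replace=True)
        for i in idx:
            planted_slots[eligible[i][0]] += 1
    # a recurrence is only planted when the same lesion's next-timepoint
    # biopsy also clears the read filter, so planted truth stays observable
    deep_by_key = {(p, l, t): sid for sid, p, l, t, st, d in plan
                   if st == "biopsy" and d >= config.min_sample_reads}

    records: list[ClonotypeRecord] = []
    metadata: list[SampleMetadata] = []
    expansion_rows = []
    sample_rows = []

    # per-patient usage history: clone -> set of (location, timepoint)
    history: dict[str, dict[tuple[str, str], set]] = {pid: {} for pid in patients}
    public_lookup = set(public)

    # generate in timepoint order so same-time sharing accumulates within a
    # procedure as its samples are drawn
    plan.sort(key=lambda s: (s[1], s[3], s[4], s[2]))
    for sid, pid, loc, tp, stype, depth in plan:
        if stype == "biopsy":
            subtype, outcome = lesion_info[(pid, loc)]
        else:
            subtype, outcome = None, "unknown"
        eff = config.outcome_effect if outcome == "regressive" else 1.0
        n_unique = int(round(config.unique_rate * eff * depth**config.unique_exponent))
        n_unique = max(2, min(n_unique, depth))

        pool = public + private[pid]
        n_pub, n_priv = len(public), len(private[pid])
        # base weights chosen so the aggregate public mass equals p_public_draw
        w = np.empty(len(pool))
        if config.p_public_draw >= 1.0:
            w[:n_pub] = 1.0
            w[n_pub:] = 0.0
        elif config.p_public_draw <= 0.0:
            w[:n_pub] = 0.0
            w[n_pub:] = 1.0
        else:
            w[:n_pub] = (config.p_public_draw / (1.0 - config.p_public_draw)) * (n_priv / n_pub)
            w[n_pub:] = 1.0
        hist = history[pid]
        for j, clone in enumerate(pool):
            uses = hist.get(clone)
            if uses:
                boost = config.within_patient_overlap_boost
                if any(u[1] == tp for u in uses):
                    boost *= config.same_time_boost
                if any(u[0] == loc for u in uses):
                    boost *= config.same_location_boost
                w[j] *= boost

        n_unique = min(n_unique, int(np.count_nonzero(w)))
        chosen = rng.choice(len(pool), size=n_unique, replace=False, p=w / w.sum())
        chosen_set = {pool[j] for j in chosen}
        planted_here = set(forced[sid])
        chosen_set |= planted_here

        # fill this sample's expansion slots, weighted toward previously used
        # and public clones
        n_slots = planted_slots[sid]
        if n_slots:
            candidates = sorted(chosen_set - planted_here)
            wts = np.ones(len(candidates))
            for j, c in enumerate(candidates):
                if c in hist:
                    wts[j] *= config.expanded_reuse_weight
                if c in public_lookup:
                    wts[j] *= config.public_expansion_weight
            k = min(n_slots, len(candidates))
            pick_idx = rng.choice(len(candidates), size=k, replace=False, p=wts / wts.sum())
            picks = [candidates[int(j)] for j in pick_idx]
            nxt = deep_by_key.get((pid, loc, tp + 1))
            for clone in picks:
                planted_here.add(clone)
                if nxt is not None and rng.random() < config.p_recurrent_expansion:
                    if clone not in forced[nxt]:
                        forced[nxt].append(clone)
                        recurrent_rows.append(
                            {"patient_id": pid, "location": loc, "chain": clone[0], "cdr3_aa": clone[1]}
                        )
        chosen_clones = sorted(chosen_set)

        alpha = np.full(len(chosen_clones), config.dirichlet_concentration)
        for j, clone in enumerate(chosen_clones):
            if clone in planted_here:
                alpha[j] *= config.expansion_fold
        p = rng.dirichlet(alpha)
        counts = rng.multinomial(depth, p)

        for clone, cnt in zip(chosen_clones, counts):
            if cnt == 0:
                continue
            records.append(
                ClonotypeRecord(sample_id=sid, cdr3_aa=clone[1], read_count=int(cnt), chain=clone[0])
            )
            hist.setdefault(clone, set()).add((loc, tp))
            if clone in planted_here:
                expansion_rows.append(
                    {"sample_id": sid, "chain": clone[0], "cdr3_aa": clone[1]}
                )

        metadata.append(
            SampleMetadata(
                sample_id=sid, patient_id=pid, location=loc, timepoint=tp,
                sample_type=stype, subtype=subtype, outcome=outcome,
            )
        )
        realized = np.sum(counts > 0)
        cpk = realized / depth * 1000.0
        score = -config.module_score_slope * (cpk / 100.0) + rng.normal(0.0, config.module_score_noise_sd)
        sample_rows.append(
            {"sample_id": sid, "sample_type": stype, "outcome": outcome,
             "module_score": score, "depth": depth}
        )

    cohort = build_cohort(records, metadata)

    public_set = set(public)
    clin_rows = []
    seen = set()
    for clone in cohort.iter_keys(cohort.records):
        if clone in seen:
            continue
        seen.add(clone)
        if clone in public_set:
            origin = "public"
        else:
            origin = next(pid for pid in patients if clone in set(private[pid]))
        clin_rows.append(
            {"chain": clone[0], "cdr3_aa": clone[1], "public": clone in public_set, "origin": origin}
        )

    truth = GroundTruth(
        clonotypes=pd.DataFrame(clin_rows, columns=["chain", "cdr3_aa", "public", "origin"]),
        expansions=pd.DataFrame(expansion_rows, columns=["sample_id", "chain", "cdr3_aa"]),
        samples=pd.DataFrame(sample_rows, columns=["sample_id", "sample_type", "outcome", "module_score", "depth"]),
        recurrent=pd.DataFrame(recurrent_rows, columns=["patient_id", "location", "chain", "cdr3_aa"]).drop_duplicates(),
    )
    scores = truth.samples.loc[truth.samples["sample_type"] == "biopsy", ["sample_id", "module_score"]].reset_index(
        drop=True
    )
    return cohort, truth, scores


def generate_reference_set(config: SyntheticConfig, n_subjects: int = 666, ref_seed: int | None = None) -> list[str]:
    """Stand-in for an external healthy-donor beta-chain CDR3 list.

    Contains every beta clone of the cohort's public pool plus decoy
    sequences; the decoy count grows with ``n_subjects``. ``ref_seed``
    controls only the decoys, so changing it keeps the public core fixed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config.validate()
    pool_rng = np.random.default_rng(config.seed)
    public, _ = _make_pools(config, pool_rng)
    core = sorted(seq for chain, seq in public if chain == "TRB")

    decoy_rng = np.random.default_rng(config.seed + 1 if ref_seed is None else ref_seed)
    taken = set(core)
    n_decoys = 3 * n_subjects
    decoys = _random_cdr3(decoy_rng, taken, n_decoys)
    return core + sorted(decoys)


def generate_annotation_db(
    config: SyntheticConfig, db_seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stand-in antigen-specificity databases.

    Returns (mcpas_like, vdjdb_like) tables; public-pool clones are annotated
    at ``db_hit_rate_public`` and private clones at ``db_hit_rate_private``,
    so enrichment of database hits among public clonotypes holds by
    construction. An annotated clone lands in one or both tables.
    """
    config.validate()
    pool_rng = np.random.default_rng(config.seed)
    public, private = _make_pools(config, pool_rng)
    rng = np.random.default_rng(config.seed + 2 if db_seed is None else db_seed)

    mcpas_rows, vdjdb_rows = [], []
    for clones, rate in ((public, config.db_hit_rate_public),
                         ([c for pool in private.values() for c in pool], config.db_hit_rate_private)):
        for chain, seq in clones:
            if rng.random() >= rate:
                continue
            species, antigen = _ANTIGENS[int(rng.integers(len(_ANTIGENS)))]
            which = rng.random()
            if which < 2 / 3:  # mcpas only or both
                col = "CDR3.beta.aa" if chain == "TRB" else "CDR3.alpha.aa"
                mcpas_rows.append({"CDR3.beta.aa": seq if col == "CDR3.beta.aa" else None,
                                   "CDR3.alpha.aa": seq if col == "CDR3.alpha.aa" else None,
                                   "Pathology": species, "Antigen.protein": antigen})
            if which > 1 / 3:  # vdjdb only or both
                vdjdb_rows.append({"cdr3": seq, "gene": chain,
                                   "antigen.epitope": antigen, "antigen.species": species})

    mcpas = pd.DataFrame(mcpas_rows, columns=["CDR3.beta.aa", "CDR3.alpha.aa", "Pathology", "Antigen.protein"])
    vdjdb = pd.DataFrame(vdjdb_rows, columns=["cdr3", "gene", "antigen.epitope", "antigen.species"])
    return mcpas, vdjdb


def generate_expression(
    scores: pd.DataFrame,
    n_module_genes: int = 25,
    n_background_genes: int = 75,
    gene_noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene-expression matrix (genes x samples) realizing given module scores.

    Module genes are the per-sample score plus independent gene-level noise;
    background genes are pure noise. Returns the matrix and the module gene
    set, ready for :func:`pmltcr.diversity.metagene_score`.
    """
    rng = np.random.default_rng(seed)
    sample_ids = scores["sample_id"].tolist()
    s = scores["module_score"].to_numpy(dtype=float)
    module_genes = [f"IMM{i + 1:03d}" for i in range(n_module_genes)]
    background = [f"BG{i + 1:03d}" for i in range(n_background_genes)]
    rows = {}
    for g in module_genes:
        rows[g] = s + rng.normal(0.0, gene_noise_sd, size=s.size)
    for g in background:
        rows[g] = rng.normal(0.0, 1.0, size=s.size)
    expr = pd.DataFrame(rows, index=sample_ids).T
    return expr, module_genes
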