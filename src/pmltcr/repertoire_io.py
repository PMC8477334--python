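"""Reading, filtering and assembling clonotype tables.

Two table dialects are supported: the AIRR Rearrangement TSV (the canonical
interchange format) and a TRUST-style TSV as produced by RNA-seq CDR3
assembly. Records shorter than six amino acids are removed before analysis,
and CDR3 strings containing stop codons ('*') or ambiguous residues ('X') are
dropped at read time, since non-productive or ambiguous assemblies cannot be
matched across samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
CHAINS = ("TRA", "TRB", "TRG", "TRD", "unknown")

AIRR_COLUMNS = ["repertoire_id", "junction_aa", "junction", "locus", "v_call", "j_call", "duplicate_count"]
_AIRR_REQUIRED = ["repertoire_id", "junction_aa", "duplicate_count"]
_TRUST_REQUIRED = ["sample", "count", "CDR3aa"]

__all__ = [
    "ClonotypeRecord",
    "SampleMetadata",
    "CohortRepertoire",
    "SchemaError",
    "RowParseError",
    "read_clonotype_table",
    "read_metadata",
    "filter_short_cdr3",
    "build_cohort",
    "write_airr",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowParseError(ValueError):
    """A row of an input table could not be parsed; carries the line number."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One observed CDR3 in one sample with its supporting read count."""

    sample_id: str
    cdr3_aa: str
    read_count: int
    chain: str = "unknown"
    cdr3_nt: str | None = None
    v_call: str | None = None
    j_call: str | None = None

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError(f"read_count must be >= 1, got {self.read_count}")
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        bad = set(self.cdr3_aa) - AA_ALPHABET
        if bad:
            raise ValueError(f"cdr3_aa contains non-amino-acid characters {sorted(bad)}")

    def key(self, pool_chains: bool = False):
        """Clonotype identity key: (chain, cdr3_aa), or cdr3_aa alone when
        chains are pooled."""
        return self.cdr3_aa if pool_chains else (self.chain, self.cdr3_aa)


@dataclass(frozen=True)
class SampleMetadata:
    """Clinical annotation of one sample.

    ``timepoint`` is the ordinal index of the screening procedure; ``outcome``
    labels the lesion's fate over follow-up.
    """

    sample_id: str
    patient_id: str
    location: str
    timepoint: int
    sample_type: str = "biopsy"
    subtype: str | None = None
    outcome: str = "unknown"

    def __post_init__(self) -> None:
        if self.sample_type not in ("biopsy", "brush"):
            raise ValueError(f"sample_type must be biopsy or brush, got {self.sample_type!r}")
        if self.outcome not in ("progressive/persistent", "regressive", "unknown"):
            raise ValueError(f"unrecognized outcome {self.outcome!r}")


_RECORD_COLUMNS = ["sample_id", "chain", "cdr3_aa", "cdr3_nt", "v_call", "j_call", "read_count"]
_META_COLUMNS = ["sample_id", "patient_id", "location", "timepoint", "sample_type", "subtype", "outcome"]


class CohortRepertoire:
    """All clonotype records of a cohort plus sample metadata.

    ``records`` is a DataFrame with one row per (sample, clonotype) after
    aggregation of duplicate rows; ``samples`` holds one metadata row per
    sample. The clonotype universe and per-sample totals are computed once at
    construction.
    """

    def __init__(self, records: pd.DataFrame, samples: pd.DataFrame, pool_chains: bool = False):
        self.records = records.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)
        self.pool_chains = pool_chains
        known = set(self.samples["sample_id"])
        orphans = sorted(set(self.records["sample_id"]) - known)
        if orphans:
            raise ValueError(f"records reference samples absent from metadata: {orphans}")
        biopsies = self.samples[self.samples["sample_type"] == "biopsy"]
        dup = biopsies.duplicated(subset=["patient_id", "location", "timepoint"])
        if dup.any():
            raise ValueError("multiple biopsies share a (patient, location, timepoint)")

    @property
    def key_columns(self) -> list[str]:
        return ["cdr3_aa"] if self.pool_chains else ["chain", "cdr3_aa"]

    @property
    def universe(self) -> frozenset:
        """Distinct clonotype keys across all records."""
        return frozenset(self.iter_keys(self.records))

    def iter_keys(self, df: pd.DataFrame):
        if self.pool_chains:
            return df["cdr3_aa"].tolist()
        return list(zip(df["chain"], df["cdr3_aa"]))

    @property
    def sample_totals(self) -> pd.DataFrame:
        """Per-sample total_reads and unique_clonotypes (zero rows for
        samples with no records)."""
        g = self.records.groupby("sample_id")
        totals = pd.DataFrame(
            {
                "total_reads": g["read_count"].sum(),
                "unique_clonotypes": g.size(),
            }
        )
        out = totals.reindex(self.samples["sample_id"]).fillna(0).astype(int)
        out.index.name = "sample_id"
        return out.reset_index()

    def sample_keys(self, sample_id: str) -> frozenset:
        df = self.records[self.records["sample_id"] == sample_id]
        return frozenset(self.iter_keys(df))

    def subset_samples(self, sample_ids: Iterable[str]) -> "CohortRepertoire":
        keep = set(sample_ids)
        return CohortRepertoire(
            self.records[self.records["sample_id"].isin(keep)],
            self.samples[self.samples["sample_id"].isin(keep)],
            pool_chains=self.pool_chains,
        )

    def subset_type(self, sample_type: str) -> "CohortRepertoire":
        ids = self.samples.loc[self.samples["sample_type"] == sample_type, "sample_id"]
        return self.subset_samples(ids)

    def drop_clonotypes(self, keys: Iterable) -> "CohortRepertoire":
        """Remove the given clonotype keys cohort-wide (used for the
        private-only sensitivity rerun)."""
        drop = set(keys)
        mask = [k not in drop for k in self.iter_keys(self.records)]
        return CohortRepertoire(self.records[mask], self.samples, pool_chains=self.pool_chains)

    def to_records(self) -> list[ClonotypeRecord]:
        out = []
        for row in self.records.itertuples(index=False):
            out.append(
                ClonotypeRecord(
                    sample_id=row.sample_id,
                    cdr3_aa=row.cdr3_aa,
                    read_count=int(row.read_count),
                    chain=row.chain,
                    cdr3_nt=row.cdr3_nt if isinstance(row.cdr3_nt, str) else None,
                    v_call=row.v_call if isinstance(row.v_call, str) else None,
                    j_call=row.j_call if isinstance(row.j_call, str) else None,
                )
            )
        return out

    def __repr__(self) -> str:
        return (
            f"CohortRepertoire({len(self.samples)} samples, {len(self.records)} records, "
            f"{len(self.universe)} clonotypes)"
        )


def _clean_cdr3(values: pd.Series) -> pd.Series:
    ok = values.astype(str).map(lambda s: len(s) > 0 and set(s) <= AA_ALPHABET)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropped %d rows with stop-codon/ambiguous/empty CDR3", n_bad)
    return ok


def _parse_counts(raw: pd.Series, path, round_half_up: bool) -> pd.Series:
    counts = []
    for line_offset, (idx, value) in enumerate(raw.items()):
        try:
            x = float(value)
        except (TypeError, ValueError):
            # +2: one for the header line, one for 1-based numbering
            raise RowParseError(f"{path}: line {idx + 2}: unparseable count {value!r}") from None
        if math.isnan(x):
            raise RowParseError(f"{path}: line {idx + 2}: unparseable count {value!r}")
        counts.append(int(math.floor(x + 0.5)) if round_half_up else int(x))
    return pd.Series(counts, index=raw.index)


def read_clonotype_table(path, dialect: str = "airr") -> list[ClonotypeRecord]:
    """Read a clonotype table into records.

    Parameters
    ----------
    path
        TSV file in either dialect.
    dialect
        ``"airr"`` (AIRR Rearrangement columns) or ``"trust"`` (TRUST-style
        columns; '#'-comment lines skipped, fractional read estimates rounded
        half-up to integers).

    Rows with zero or negative counts and rows whose CDR3 contains characters
    outside the 20-letter amino-acid alphabet are dropped with a logged count.
    """
    path = Path(path)
    if dialect == "airr":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _AIRR_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required AIRR column(s): {missing}")
        if df.empty:
            return []
        df = df.rename(
            columns={
                "repertoire_id": "sample_id",
                "junction_aa": "cdr3_aa",
                "junction": "cdr3_nt",
                "locus": "chain",
            }
        )
        df["read_count"] = _parse_counts(df["duplicate_count"], path, round_half_up=False)
    elif dialect == "trust":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        missing = [c for c in _TRUST_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required TRUST column(s): {missing}")
        if df.empty:
            return []
        df = df.rename(
            columns={
                "sample": "sample_id",
                "CDR3aa": "cdr3_aa",
                "CDR3nt": "cdr3_nt",
                "Vgene": "v_call",
                "Jgene": "j_call",
            }
        )
        df["read_count"] = _parse_counts(df["count"], path, round_half_up=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in ("chain", "cdr3_nt", "v_call", "j_call"):
        if col not in df.columns:
            df[col] = None
    df["chain"] = df["chain"].map(lambda c: c if c in CHAINS[:4] else "unknown")

    nonpos = df["read_count"] < 1
    if nonpos.any():
        logger.info("dropped %d rows with zero/negative counts", int(nonpos.sum()))
        df = df[~nonpos]
    df = df[_clean_cdr3(df["cdr3_aa"])]

    return [
        ClonotypeRecord(
            sample_id=row.sample_id,
            cdr3_aa=row.cdr3_aa,
            read_count=int(row.read_count),
            chain=row.chain,
            cdr3_nt=row.cdr3_nt if isinstance(row.cdr3_nt, str) and row.cdr3_nt else None,
            v_call=row.v_call if isinstance(row.v_call, str) and row.v_call else None,
            j_call=row.j_call if isinstance(row.j_call, str) and row.j_call else None,
        )
        for row in df.itertuples(index=False)
    ]


def read_metadata(path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (sample_id, patient_id, location,
    timepoint, sample_type, subtype, outcome)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "patient_id", "location", "timepoint") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required metadata column(s): {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleMetadata(
                sample_id=row.sample_id,
                patient_id=row.patient_id,
                location=row.location,
                timepoint=int(row.timepoint),
                sample_type=getattr(row, "sample_type", "biopsy") or "biopsy",
                subtype=getattr(row, "subtype", None) if isinstance(getattr(row, "subtype", None), str) else None,
                outcome=getattr(row, "outcome", "unknown") or "unknown",
            )
        )
    return out


def filter_short_cdr3(records: Sequence[ClonotypeRecord], min_aa: int = 6) -> list[ClonotypeRecord]:
    """Drop records whose CDR3 is shorter than ``min_aa`` amino acids,
    preserving order. Short assemblies are unreliable and excluded from all
    analyses."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    kept = [r for r in records if len(r.cdr3_aa) >= min_aa]
    logger.info("CDR3 length filter (>= %d aa): %d -> %d records", min_aa, len(records), len(kept))
    return kept


def build_cohort(
    records: Sequence[ClonotypeRecord],
    metadata: Sequence[SampleMetadata],
    pool_chains: bool = False,
) -> CohortRepertoire:
    """Assemble records + metadata into a :class:`CohortRepertoire`.

    Duplicate rows for the same (sample, clonotype key) are summed into one
    record. Records whose sample_id has no metadata raise an error listing the
    offenders.
    """
    meta_df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "location": m.location,
                "timepoint": m.timepoint,
                "sample_type": m.sample_type,
                "subtype": m.subtype,
                "outcome": m.outcome,
            }
            for m in metadata
        ],
        columns=_META_COLUMNS,
    )
    rec_df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "chain": r.chain,
                "cdr3_aa": r.cdr3_aa,
                "cdr3_nt": r.cdr3_nt,
                "v_call": r.v_call,
                "j_call": r.j_call,
                "read_count": r.read_count,
            }
            for r in records
        ],
        columns=_RECORD_COLUMNS,
    )
    if not rec_df.empty:
        key_cols = ["sample_id", "cdr3_aa"] if pool_chains else ["sample_id", "chain", "cdr3_aa"]
        agg = {"read_count": "sum", "cdr3_nt": "first", "v_call": "first", "j_call": "first"}
        if pool_chains:
            agg["chain"] = "first"
        rec_df = rec_df.groupby(key_cols, as_index=False, sort=True).agg(agg)
        rec_df = rec_df[_RECORD_COLUMNS]
    return CohortRepertoire(rec_df, meta_df, pool_chains=pool_chains)


def write_airr(cohort: CohortRepertoire, path) -> None:
    """Write the cohort's records as an AIRR Rearrangement TSV.

    Chain ``"unknown"`` is emitted as an empty locus field. Reading the file
    back reproduces the record multiset.
    """
    df = cohort.records.copy()
    out = pd.DataFrame(
        {
            "repertoire_id": df["sample_id"],
            "junction_aa": df["cdr3_aa"],
            "junction": df["cdr3_nt"],
            "locus": df["chain"].map(lambda c: "" if c == "unknown" else c),
            "v_call": df["v_call"],
            "j_call": df["j_call"],
            "duplicate_count": df["read_count"],
        },
        columns=AIRR_COLUMNS,
    )
    out.to_csv(path, sep="\t", index=False, na_rep="")


def write_metadata(cohort: CohortRepertoire, path) -> None:
    """Write the sample metadata TSV alongside the AIRR file."""
    cohort.samples.to_csv(path, sep="\t", index=False, na_rep="")
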