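"""Domain containers and file I/O for the episignature pipeline.

The pipeline operates on three tabular objects: a beta-value matrix
(probes x samples, methylation fractions in [0, 1]), a sample sheet
describing each individual (group, cohort role, sex, chronological age),
and a probe manifest carrying the array annotation needed for quality
control and region enrichment (coordinates, probe class, CpG-island
relation, SNP/cross-reactivity flags, gene spans).

All containers wrap :class:`pandas.DataFrame` and validate their
invariants on construction, so downstream modules can rely on unique
identifiers and in-range values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("case", "control")
ROLES = (
    "discovery_case",
    "discovery_control",
    "validation_case",
    "validation_control",
    "test",
)
SEXES = ("F", "M")
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
PROBE_CLASSES = ("cg", "ch", "rs")

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


class EpisigError(ValueError):
    """Base error for malformed inputs."""


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions.

    ``values`` is indexed by probe id with one column per sample id.
    Missing measurements are carried as NaN; every non-missing entry
    must lie in [0, 1].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise EpisigError(f"duplicate probe ids: {dups[:5]}")
        if vals.columns.has_duplicates:
            dups = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise EpisigError(f"duplicate sample ids: {dups[:5]}")
        arr = vals.to_numpy(dtype=float)
        bad = np.nonzero(~np.isnan(arr) & ((arr < 0.0) | (arr > 1.0)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise EpisigError(
                f"beta value {arr[i, j]} outside [0, 1] at probe "
                f"{vals.index[i]!r}, sample {vals.columns[j]!r}"
            )
        self.values = vals.astype(float).rename_axis(index=None, columns=None)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise EpisigError(f"probes absent from matrix: {missing[:5]}")
        return BetaMatrix(self.values.loc[list(probes)])

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise EpisigError(f"samples absent from matrix: {missing[:5]}")
        return BetaMatrix(self.values[list(samples)])


def read_beta_matrix(path: str | Path, dialect: str | None = None) -> BetaMatrix:
    """Read a probes x samples beta matrix from TSV or CSV.

    ``dialect`` is "tsv" or "csv"; when omitted it is inferred from the
    file suffix (default TSV). The first column holds probe ids and the
    header row holds sample ids. Empty cells become missing values.
    """
    path = Path(path)
    sep = _resolve_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_bad = coerced.isna() & df[col].notna()
            if newly_bad.any():
                probe = df.index[newly_bad.argmax()]
                raise EpisigError(
                    f"non-numeric beta {df.loc[probe, col]!r} at probe "
                    f"{probe!r}, sample {col!r}"
                )
            df[col] = coerced
    return BetaMatrix(df)


def write_beta_matrix(
    beta: BetaMatrix, path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    sep = _resolve_sep(path, dialect)
    beta.values.to_csv(path, sep=sep, index_label="probe_id")


def _resolve_sep(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise EpisigError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Per-sample metadata: group, cohort role, sex and age in years.

    Ages are continuous (a 2-day-old is ~0.0055 years) because the
    epigenetic-clock transform operates on real-valued age. Only samples
    with a ``discovery_*`` role may enter model fitting; the other roles
    are scored against the fitted models. Extra columns (e.g. a cohort
    label) are carried through untouched.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "role", "sex", "age_years")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise EpisigError(f"sample sheet missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise EpisigError(f"duplicate sample ids: {dups[:5]}")
        bad_group = set(t["group"]) - set(GROUPS)
        if bad_group:
            raise EpisigError(f"unknown group labels: {sorted(bad_group)}")
        bad_role = set(t["role"]) - set(ROLES)
        if bad_role:
            raise EpisigError(f"unknown role labels: {sorted(bad_role)}")
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_sex:
            raise EpisigError(f"unknown sex labels: {sorted(bad_sex)}")
        ages = t["age_years"].astype(float)
        if (ages < 0).any():
            raise EpisigError("negative age_years in sample sheet")
        t = t.copy()
        t["age_years"] = ages
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def subset(self, mask_or_ids) -> "SampleSheet":
        """Subset by boolean mask, or by an id list (preserving its order)."""
        if isinstance(mask_or_ids, (list, tuple, pd.Index, np.ndarray)) and not (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool
        ):
            ids = list(mask_or_ids)
            missing = set(ids) - set(self.table["sample_id"])
            if missing:
                raise EpisigError(f"unknown sample ids: {sorted(missing)[:5]}")
            sub = self.table.set_index("sample_id").loc[ids].reset_index()
            return SampleSheet(sub)
        return SampleSheet(self.table.loc[mask_or_ids].reset_index(drop=True))

    def with_role(self, *roles: str) -> "SampleSheet":
        return self.subset(self.table["role"].isin(roles).to_numpy())

    def discovery(self) -> "SampleSheet":
        return self.with_role("discovery_case", "discovery_control")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpan:
    symbol: str
    start: int
    end: int
    strand: str = "."


@dataclass
class ProbeManifest:
    """Array annotation: coordinates, probe class, island relation, flags.

    ``table`` is indexed by probe id with columns ``chrom``, ``pos``
    (1-based), ``probe_class`` (cg/ch/rs), ``island_relation``
    (Island/Shore/Shelf/OpenSea; a Shore lies within 2 kb of an Island),
    ``snp_maf`` (minor-allele frequency of a nearby SNP, NaN when none),
    ``cross_reactive`` (bool) and ``genes`` (list of :class:`GeneSpan`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise EpisigError("duplicate probe ids in manifest")
        if (t["pos"] < 1).any():
            raise EpisigError("manifest positions must be 1-based (>= 1)")
        bad = set(t["island_relation"]) - set(ISLAND_RELATIONS)
        if bad:
            raise EpisigError(f"unknown island relations: {sorted(bad)}")
        bad = set(t["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise EpisigError(f"unknown probe classes: {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def require(self, probes: Iterable[str]) -> pd.DataFrame:
        probes = list(probes)
        missing = [p for p in probes if p not in self.table.index]
        if missing:
            raise EpisigError(f"probes absent from manifest: {missing[:10]}")
        return self.table.loc[probes]


MANIFEST_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "probe_class",
    "island_relation",
    "snp_maf",
    "cross_reactive",
    "genes",
)


def _format_genes(genes: Sequence[GeneSpan]) -> str:
    return ";".join(f"{g.symbol}|{g.start}|{g.end}|{g.strand}" for g in genes)


def _parse_genes(cell) -> list[GeneSpan]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    spans = []
    for chunk in str(cell).split(";"):
        sym, start, end, strand = chunk.split("|")
        spans.append(GeneSpan(sym, int(start), int(end), strand))
    return spans


def read_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    df = df.set_index("probe_id")
    df["snp_maf"] = pd.to_numeric(df.get("snp_maf"), errors="coerce")
    df["cross_reactive"] = (
        df["cross_reactive"].astype(str).str.lower().isin(("1", "true", "yes"))
    )
    df["genes"] = [_parse_genes(c) for c in df.get("genes", pd.Series("", df.index))]
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    df = manifest.table.copy()
    df["cross_reactive"] = df["cross_reactive"].astype(int)
    df["genes"] = [_format_genes(g) for g in df["genes"]]
    df.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Alignment and cohort summaries
# ---------------------------------------------------------------------------


def align(beta: BetaMatrix, sheet: SampleSheet) -> BetaMatrix:
    """Restrict ``beta`` to samples in ``sheet``, in sheet order.

    Samples present in only one of the two inputs are dropped; an empty
    intersection is an error.
    """
    order = [s for s in sheet.sample_ids if s in beta.values.columns]
    if not order:
        raise EpisigError("no samples shared between beta matrix and sample sheet")
    return BetaMatrix(beta.values[order])


@dataclass(frozen=True)
class CohortSummary:
    """Demographic summary of one cohort, as printed in study tables.

    ``sd_age`` is the sample standard deviation (n - 1 denominator).
    A single-sample cohort has no defined SD; it is reported as 0 with
    ``sd_defined = False``.
    """

    n: int
    n_female: int
    n_male: int
    mean_age: float
    sd_age: float
    min_age: float
    max_age: float
    sd_defined: bool = True

    def rounded(self, decimals: int = 1) -> "CohortSummary":
        return CohortSummary(
            self.n,
            self.n_female,
            self.n_male,
            round(self.mean_age, decimals),
            round(self.sd_age, decimals),
            self.min_age,
            self.max_age,
            self.sd_defined,
        )


def summarize_cohort(
    sheet: SampleSheet, role_filter: Sequence[str] | str | None = None
) -> CohortSummary:
    """Summarize n / sex split / age mean, SD (n-1) and range for a cohort."""
    t = sheet.table
    if role_filter is not None:
        if isinstance(role_filter, str):
            role_filter = [role_filter]
        t = t[t["role"].isin(role_filter)]
    if len(t) == 0:
        raise EpisigError("no samples after role filter")
    ages = t["age_years"].to_numpy(dtype=float)
    if len(t) == 1:
        warnings.warn("single-sample cohort: SD undefined, reported as 0")
        sd, sd_defined = 0.0, False
    else:
        sd, sd_defined = float(np.std(ages, ddof=1)), True
    return CohortSummary(
        n=len(t),
        n_female=int((t["sex"] == "F").sum()),
        n_male=int((t["sex"] == "M").sum()),
        mean_age=float(np.mean(ages)),
        sd_age=sd,
        min_age=float(ages.min()),
        max_age=float(ages.max()),
        sd_defined=sd_defined,
    )


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------


def export_signature_bed(result, manifest: ProbeManifest, path: str | Path) -> None:
    """Write signature CpGs as BED6 (0-based half-open, score = |dbeta| x 1000).

    Manifest coordinates are 1-based (Illumina convention), so a probe
    at position ``pos`` becomes the interval ``[pos - 1, pos)``.
    ``result`` is a :class:`episig.signature.DiffMethResult` restricted
    to the signature, or any DataFrame with a ``delta_beta`` column
    indexed by probe id.
    """
    table = result.table if hasattr(result, "table") else result
    path = Path(path)
    probes = list(table.index)
    with path.open("w") as fh:
        fh.write("# signature CpGs, BED6, score = min(1, |delta beta|) * 1000\n")
        if not probes:
            return
        ann = manifest.require(probes)
        for probe in probes:
            row = ann.loc[probe]
            score = int(round(min(1.0, abs(float(table.loc[probe, "delta_beta"]))) * 1000))
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) - 1}\t{int(row['pos'])}"
                f"\t{probe}\t{score}\t.\n"
            )


def read_bed_probes(path: str | Path) -> pd.DataFrame:
    """Read back a BED6 export (names and 0-based coordinates)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, name, score, strand = line.split("\t")
        rows.append((name, chrom, int(start), int(end), int(score), strand))
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "score", "strand"]
    ).set_index("probe_id")
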