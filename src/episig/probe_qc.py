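"""Probe-level quality control for methylation arrays.

Six exclusion rules are applied, in a fixed order, to produce the
analysis-ready probe set:

1. detection failures (detection p-value above threshold in too many
   samples),
2. probes near common SNPs (minor-allele frequency > 1%),
3. cross-reactive probes (multi-mapping, per published blacklists,
   consumed here as a manifest flag),
4. probes with raw beta exactly 0 or 1 in more than 0.25% of samples,
5. non-CpG probes (ch / rs classes),
6. X- and Y-chromosome probes.

The rule categories overlap on real arrays, so the report keeps two
counts per rule: how many probes *match* the rule at all, and how many
are *incrementally removed* by it given the rules applied before it.
Only the incremental counts sum to the total removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, EpisigError, ProbeManifest, SEX_CHROMOSOMES

RULE_ORDER = (
    "detection",
    "snp",
    "cross_reactive",
    "extreme_beta",
    "non_cpg",
    "sex_chromosome",
)


@dataclass
class QCParams:
    """Thresholds for the exclusion rules.

    detection_p: a probe fails detection in a sample when its detection
        p-value exceeds this (default 0.01).
    detection_fraction: fraction of samples that must fail for the probe
        to be excluded; the default 0.0 means "any sample".
    snp_maf: probes with an annotated SNP above this minor-allele
        frequency are excluded (default 0.01).
    extreme_fraction: probes with raw beta of exactly 0 or 1 in more
        than this fraction of samples are excluded (default 0.0025);
        with 34 samples the cutoff 0.085 means one endpoint value
        already triggers removal.
    extreme_tol: tolerance around the 0/1 endpoints (default 0, exact
        equality after parsing).
    """

    detection_p: float = 0.01
    detection_fraction: float = 0.0
    snp_maf: float = 0.01
    extreme_fraction: float = 0.0025
    extreme_tol: float = 0.0


@dataclass
class FilterReport:
    """Per-rule accounting of probe removals."""

    n_input: int
    n_remaining: int
    matched_count: dict[str, int] = field(default_factory=dict)
    removed_count: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total_removed = sum(self.removed_count.values())
        if self.n_remaining != self.n_input - total_removed:
            raise EpisigError("filter report counts inconsistent")
        for rule, rem in self.removed_count.items():
            if rem > self.matched_count.get(rule, 0):
                raise EpisigError(f"rule {rule}: removed > matched")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_remaining": self.n_remaining,
            "matched_count": dict(self.matched_count),
            "removed_count": dict(self.removed_count),
        }


def flag_detection_failures(
    detp: pd.DataFrame,
    p_threshold: float = 0.01,
    sample_fraction: float = 0.0,
) -> set[str]:
    """Return probes whose detection p > threshold in enough samples.

    ``sample_fraction`` is the minimum fraction of samples that must
    fail; 0 means a single failing sample suffices.
    """
    if not (0 < p_threshold <= 1):
        raise EpisigError("p_threshold must be in (0, 1]")
    if not (0 <= sample_fraction <= 1):
        raise EpisigError("sample_fraction must be in [0, 1]")
    n = detp.shape[1]
    fail_frac = (detp.to_numpy(dtype=float) > p_threshold).sum(axis=1) / n
    needed = max(sample_fraction, 1.0 / n)  # at least one sample
    flagged = detp.index[fail_frac >= needed]
    return set(flagged)


def _rule_matches(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    detp: pd.DataFrame | None,
    params: QCParams,
) -> dict[str, set[str]]:
    probes = beta.probe_ids
    ann = manifest.require(probes)
    matches: dict[str, set[str]] = {}

    if detp is not None:
        if set(detp.index) != set(probes) or detp.shape[1] != beta.shape[1]:
            raise EpisigError("detection p-value matrix not aligned to beta matrix")
        matches["detection"] = flag_detection_failures(
            detp, params.detection_p, params.detection_fraction
        )
    else:
        matches["detection"] = set()

    maf = ann["snp_maf"]
    matches["snp"] = set(ann.index[maf.notna() & (maf > params.snp_maf)])
    matches["cross_reactive"] = set(ann.index[ann["cross_reactive"]])

    arr = beta.values.to_numpy(dtype=float)
    tol = params.extreme_tol
    extreme = (arr <= tol) | (arr >= 1.0 - tol)
    frac = np.nansum(extreme, axis=1) / beta.shape[1]
    matches["extreme_beta"] = set(probes[frac > params.extreme_fraction])

    matches["non_cpg"] = set(ann.index[ann["probe_class"] != "cg"])
    matches["sex_chromosome"] = set(
        ann.index[ann["chrom"].astype(str).isin(SEX_CHROMOSOMES)]
    )
    return matches


def filter_probes(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    detp: pd.DataFrame | None = None,
    params: QCParams | None = None,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the six exclusion rules; return the filtered matrix and report.

    Rules are applied in :data:`RULE_ORDER`. The final probe set does
    not depend on that order (each rule's match set is computed on the
    input), only the incremental removal counts do.
    """
    params = params or QCParams()
    matches = _rule_matches(beta, manifest, detp, params)

    removed_so_far: set[str] = set()
    matched_count: dict[str, int] = {}
    removed_count: dict[str, int] = {}
    for rule in RULE_ORDER:
        m = matches[rule]
        matched_count[rule] = len(m)
        newly = m - removed_so_far
        removed_count[rule] = len(newly)
        removed_so_far |= newly

    keep = [p for p in beta.probe_ids if p not in removed_so_far]
    report = FilterReport(
        n_input=beta.shape[0],
        n_remaining=len(keep),
        matched_count=matched_count,
        removed_count=removed_count,
    )
    return beta.subset_probes(keep), report
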