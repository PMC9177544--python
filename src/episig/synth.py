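"""Synthetic cohort generator with the statistical structure of blood DNAm.

Every pipeline stage can be exercised without any external download:
the generator emits a beta matrix, sample sheet, probe manifest,
cell-type reference panel, clock model, and truth tables recording what
was planted.

The generative model, per probe p and sample s:

* background probes: ``beta = expit(logit(m_p) + cell effect + noise)``
  with the baseline mean ``m_p`` drawn from a bimodal distribution
  (mostly-methylated / mostly-unmethylated, as on real arrays) and
  Gaussian noise on the logit scale;
* signature probes: case samples additionally receive a logit shift
  calibrated so that the realized mean beta difference equals the
  configured delta beta exactly at the baseline (shift =
  logit(m + delta) - logit(m)), with a signed mix of directions;
* deconvolution probes: ``beta = R pi_s + noise`` where ``R`` is the
  cell-type reference panel and ``pi_s`` the sample's Dirichlet-drawn
  6-type composition — mixtures of cell profiles are linear on the
  beta scale, so these probes are generated there;
* clock probes: ``beta = mu_p + a_p * T(effective age) + noise`` with
  weights arranged so the clock's linear predictor equals the
  transformed effective age; cases get ``effective age = age +
  planted acceleration``. The clock effect is linear on the beta scale
  by construction, since the clock itself is a linear model on betas.

An optional second, disjoint "other syndrome" signature supports
specificity tests (cohorts that are epigenetically abnormal but not
case-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cell_deconv import DEFAULT_CELL_TYPES, CellReference
from .core_io import (
    BetaMatrix,
    EpisigError,
    GeneSpan,
    ProbeManifest,
    SampleSheet,
    write_beta_matrix,
    write_manifest,
)
from .epi_clock import ClockModel, transform_age


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the cohort design the pipeline targets: 8 discovery
    cases vs 26 matched discovery controls, 6 validation cases and 100
    validation controls, a planted signature with |delta beta| in
    [0.10, 0.25] (half hyper-, half hypomethylated), six blood cell
    types with a neutrophil-dominated Dirichlet composition, and a
    +14.4-year epigenetic-age acceleration planted in cases.
    """

    seed: int = 0
    n_probes: int = 20_000
    n_signature_cpgs: int = 150
    delta_low: float = 0.10
    delta_high: float = 0.25
    fraction_hyper: float = 0.5
    n_case: int = 8
    n_control: int = 26
    n_validation_case: int = 6
    n_validation_control: int = 100
    noise_sd: float = 0.05  # logit scale
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    dirichlet_alpha: tuple[float, ...] = (5.0, 2.5, 1.5, 2.5, 2.5, 18.0)
    n_deconv_cpgs: int = 600
    deconv_noise_sd: float = 0.01  # beta scale
    n_clock_cpgs: int = 100
    clock_noise_sd: float = 0.003  # beta scale
    adult_age: float = 20.0
    case_acceleration_years: float = 14.4
    case_acceleration_sd: float = 6.0  # between-case spread of the planted offset
    clock_residual_sd: float = 4.0  # inter-individual epigenetic-age scatter, years
    island_frac_signature: float = 0.55
    island_frac_background: float = 0.37
    n_other_signature_cpgs: int = 150
    cell_effect_fraction: float = 0.10  # background probes with composition loading
    cell_effect_sd: float = 0.5  # logit scale
    age_range_case: tuple[float, float] = (4.0, 31.0)
    age_range_control: tuple[float, float] = (4.0, 35.0)

    def validate(self) -> None:
        if min(self.n_probes, self.n_case, self.n_control) <= 0:
            raise EpisigError("probe and cohort counts must be positive")
        if not (0 < self.delta_low <= self.delta_high < 1):
            raise EpisigError("delta range must satisfy 0 < low <= high < 1")
        if len(self.cell_types) != len(self.dirichlet_alpha):
            raise EpisigError("cell_types and dirichlet_alpha lengths differ")
        reserved = (
            self.n_signature_cpgs
            + self.n_other_signature_cpgs
            + self.n_deconv_cpgs
            + self.n_clock_cpgs
        )
        if reserved >= self.n_probes:
            raise EpisigError("special probe classes exceed n_probes")


@dataclass
class SimulatedCohort:
    """A simulated study: inputs for every stage plus ground truth.

    ``truth`` holds DataFrames: ``signature`` (planted CpGs with true
    delta beta and direction), ``other_signature``, ``cell_proportions``
    (true per-sample composition), and ``ages`` (chronological and
    effective ages with the planted acceleration).
    """

    beta: BetaMatrix
    sheet: SampleSheet
    manifest: ProbeManifest
    cell_reference: CellReference
    clock: ClockModel
    truth: dict[str, pd.DataFrame]
    config: SimulationConfig
    # internal generative state, reused for extra test cohorts
    _baseline_logit: np.ndarray = field(repr=False, default=None)
    _probe_roles: pd.Series = field(repr=False, default=None)
    _case_shift: np.ndarray = field(repr=False, default=None)
    _other_shift: np.ndarray = field(repr=False, default=None)
    _cell_loadings: np.ndarray = field(repr=False, default=None)
    _clock_mu: np.ndarray = field(repr=False, default=None)
    _clock_slope: np.ndarray = field(repr=False, default=None)


def _draw_baseline_means(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal baseline: mostly-unmethylated, mostly-methylated, and mid."""
    comp = rng.choice(3, size=n, p=[0.42, 0.42, 0.16])
    m = np.empty(n)
    m[comp == 0] = rng.beta(2.0, 8.0, size=(comp == 0).sum())
    m[comp == 1] = rng.beta(8.0, 2.0, size=(comp == 1).sum())
    m[comp == 2] = rng.beta(5.0, 5.0, size=(comp == 2).sum())
    return np.clip(m, 0.02, 0.98)


def _signed_deltas(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    mag = rng.uniform(cfg.delta_low, cfg.delta_high, size=n)
    sign = np.where(rng.random(n) < cfg.fraction_hyper, 1.0, -1.0)
    return mag * sign


def _make_reference_panel(
    rng: np.random.Generator, cfg: SimulationConfig, cpg_ids: list[str]
) -> CellReference:
    """Discriminative reference: each CpG is near-distinct in one cell type."""
    k = len(cfg.cell_types)
    n = len(cpg_ids)
    base = rng.uniform(0.1, 0.9, size=n)
    R = np.tile(base[:, None], (1, k))
    owner = rng.integers(0, k, size=n)
    direction = np.where(base < 0.5, 1.0, -1.0)
    R[np.arange(n), owner] = np.clip(base + direction * rng.uniform(0.4, 0.7, n), 0.0, 1.0)
    return CellReference(pd.DataFrame(R, index=cpg_ids, columns=list(cfg.cell_types)))


def _make_clock(
    rng: np.random.Generator, cfg: SimulationConfig, cpg_ids: list[str]
) -> tuple[ClockModel, np.ndarray, np.ndarray]:
    """Clock whose predictor reproduces the transformed age exactly.

    With weights w and probe values mu_i + a_i * T, choosing
    a_i = w_i / sum(w^2) gives sum(w_i a_i) = 1, and the intercept
    -sum(w_i mu_i) makes the predictor equal T.
    """
    w = rng.uniform(0.5, 1.5, size=len(cpg_ids))
    mu = rng.uniform(0.3, 0.6, size=len(cpg_ids))
    slope = w / np.sum(w**2)
    intercept = -float(np.sum(w * mu))
    clock = ClockModel(
        intercept=intercept,
        coefficients={c: float(wi) for c, wi in zip(cpg_ids, w)},
        adult_age=cfg.adult_age,
    )
    return clock, mu, slope


def _island_relations(
    rng: np.random.Generator, n: int, island_shore_frac: float
) -> np.ndarray:
    """Assign island relations with the requested Island+Shore fraction."""
    p_is = island_shore_frac
    probs = [0.6 * p_is, 0.4 * p_is, 0.15 * (1 - p_is), 0.85 * (1 - p_is)]
    return rng.choice(
        np.array(["Island", "Shore", "Shelf", "OpenSea"]), size=n, p=probs
    )


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate the full synthetic study (deterministic given the seed)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    roles = np.array(["background"] * n, dtype=object)
    cursor = 0

    def take(count: int, label: str) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + count)
        roles[idx] = label
        cursor += count
        return idx

    sig_idx = take(cfg.n_signature_cpgs, "signature")
    other_idx = take(cfg.n_other_signature_cpgs, "other_signature")
    deconv_idx = take(cfg.n_deconv_cpgs, "deconv")
    clock_idx = take(cfg.n_clock_cpgs, "clock")

    baseline = _draw_baseline_means(rng, n)
    # signature baselines kept mid-range so m + delta stays inside (0, 1)
    deltas = _signed_deltas(rng, cfg, cfg.n_signature_cpgs)
    baseline[sig_idx] = np.where(
        deltas > 0,
        rng.uniform(0.20, 1.0 - cfg.delta_high - 0.10, size=len(sig_idx)),
        rng.uniform(cfg.delta_high + 0.10, 0.80, size=len(sig_idx)),
    )
    other_deltas = _signed_deltas(rng, cfg, cfg.n_other_signature_cpgs)
    baseline[other_idx] = np.where(
        other_deltas > 0,
        rng.uniform(0.20, 1.0 - cfg.delta_high - 0.10, size=len(other_idx)),
        rng.uniform(cfg.delta_high + 0.10, 0.80, size=len(other_idx)),
    )
    base_logit = logit(baseline)

    case_shift = np.zeros(n)
    case_shift[sig_idx] = logit(baseline[sig_idx] + deltas) - base_logit[sig_idx]
    other_shift = np.zeros(n)
    other_shift[other_idx] = (
        logit(baseline[other_idx] + other_deltas) - base_logit[other_idx]
    )

    # sparse cell-composition loadings on background probes
    k = len(cfg.cell_types)
    loadings = np.zeros((n, k))
    bg_idx = np.nonzero(roles == "background")[0]
    loaded = rng.choice(
        bg_idx, size=int(cfg.cell_effect_fraction * len(bg_idx)), replace=False
    )
    loadings[loaded] = rng.normal(0.0, cfg.cell_effect_sd, size=(len(loaded), k))

    ref = _make_reference_panel(rng, cfg, [probe_ids[i] for i in deconv_idx])
    clock, clock_mu, clock_slope = _make_clock(
        rng, cfg, [probe_ids[i] for i in clock_idx]
    )

    # ---- manifest ---------------------------------------------------------
    chroms = rng.choice([f"chr{c}" for c in range(1, 23)], size=n)
    pos = rng.integers(10_001, 50_000_000, size=n)
    island = np.empty(n, dtype=object)
    is_sig = roles == "signature"
    island[is_sig] = _island_relations(rng, int(is_sig.sum()), cfg.island_frac_signature)
    island[~is_sig] = _island_relations(
        rng, int((~is_sig).sum()), cfg.island_frac_background
    )
    genes: list[list[GeneSpan]] = [[] for _ in range(n)]
    with_gene = rng.random(n) < 0.4
    for i in np.nonzero(with_gene)[0]:
        start = max(1, int(pos[i]) - int(rng.integers(0, 15_000)))
        genes[i] = [GeneSpan(f"GENE{i % 4000}", start, start + 5_000, "+")]
    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "chrom": chroms,
                "pos": pos,
                "probe_class": "cg",
                "island_relation": island,
                "snp_maf": np.nan,
                "cross_reactive": False,
                "genes": genes,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    # ---- samples ----------------------------------------------------------
    specs = (
        [("BOS", "case", "discovery_case", cfg.n_case)]
        + [("CTRL", "control", "discovery_control", cfg.n_control)]
        + [("VBOS", "case", "validation_case", cfg.n_validation_case)]
        + [("VCTRL", "control", "validation_control", cfg.n_validation_control)]
    )
    rows = []
    for prefix, group, role, count in specs:
        for j in range(count):
            rows.append((f"{prefix}{j + 1:03d}", group, role))
    sheet_df = pd.DataFrame(rows, columns=["sample_id", "group", "role"])
    n_samp = len(sheet_df)
    sheet_df["sex"] = rng.permuted(
        np.array((["F", "M"] * n_samp)[:n_samp], dtype=object)
    )
    is_case = (sheet_df["group"] == "case").to_numpy()
    ages = np.where(
        is_case,
        rng.uniform(*cfg.age_range_case, size=n_samp),
        rng.uniform(*cfg.age_range_control, size=n_samp),
    )
    sheet_df["age_years"] = np.round(ages, 2)
    sheet_df["cohort"] = np.where(is_case, "case", "control")
    sheet = SampleSheet(sheet_df)

    props = rng.dirichlet(cfg.dirichlet_alpha, size=n_samp)
    planted_accel = np.where(
        is_case,
        rng.normal(cfg.case_acceleration_years, cfg.case_acceleration_sd, n_samp),
        0.0,
    )
    indiv = rng.normal(0.0, cfg.clock_residual_sd, n_samp)
    # effective age drives the clock CpGs; keep it positive (clip recorded in truth)
    eff_age = np.maximum(
        sheet_df["age_years"].to_numpy() + planted_accel + indiv, 0.05
    )

    values = _generate_betas(
        rng,
        cfg,
        base_logit=base_logit,
        shifts=np.where(is_case[None, :], case_shift[:, None], 0.0),
        loadings=loadings,
        props=props,
        ref=ref,
        deconv_idx=deconv_idx,
        clock_idx=clock_idx,
        clock_mu=clock_mu,
        clock_slope=clock_slope,
        eff_age=eff_age,
    )
    beta = BetaMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sheet_df["sample_id"])
    )

    truth = {
        "signature": pd.DataFrame(
            {
                "delta_beta": deltas,
                "direction": np.where(deltas > 0, "hyper", "hypo"),
            },
            index=[probe_ids[i] for i in sig_idx],
        ),
        "other_signature": pd.DataFrame(
            {
                "delta_beta": other_deltas,
                "direction": np.where(other_deltas > 0, "hyper", "hypo"),
            },
            index=[probe_ids[i] for i in other_idx],
        ),
        "cell_proportions": pd.DataFrame(
            props, index=sheet_df["sample_id"], columns=list(cfg.cell_types)
        ),
        "ages": pd.DataFrame(
            {
                "chrono_age": sheet_df["age_years"].to_numpy(),
                "effective_age": eff_age,
                "acceleration": eff_age - sheet_df["age_years"].to_numpy(),
                "planted_acceleration": planted_accel,
            },
            index=sheet_df["sample_id"],
        ),
    }
    return SimulatedCohort(
        beta=beta,
        sheet=sheet,
        manifest=manifest,
        cell_reference=ref,
        clock=clock,
        truth=truth,
        config=cfg,
        _baseline_logit=base_logit,
        _probe_roles=pd.Series(roles, index=probe_ids),
        _case_shift=case_shift,
        _other_shift=other_shift,
        _cell_loadings=loadings,
        _clock_mu=clock_mu,
        _clock_slope=clock_slope,
    )


def _generate_betas(
    rng,
    cfg: SimulationConfig,
    *,
    base_logit: np.ndarray,
    shifts: np.ndarray,
    loadings: np.ndarray,
    props: np.ndarray,
    ref: CellReference,
    deconv_idx: np.ndarray,
    clock_idx: np.ndarray,
    clock_mu: np.ndarray,
    clock_slope: np.ndarray,
    eff_age: np.ndarray,
) -> np.ndarray:
    n, n_samp = base_logit.size, props.shape[0]
    centered = props - props.mean(axis=0, keepdims=True)
    lin = base_logit[:, None] + shifts + loadings @ centered.T
    noise = rng.normal(0.0, cfg.noise_sd, size=(n, n_samp))
    values = expit(lin + noise)

    R = ref.betas.to_numpy()
    values[deconv_idx] = np.clip(
        R @ props.T + rng.normal(0.0, cfg.deconv_noise_sd, size=(len(deconv_idx), n_samp)),
        0.0,
        1.0,
    )
    T = transform_age(eff_age, cfg.adult_age)
    values[clock_idx] = np.clip(
        clock_mu[:, None]
        + clock_slope[:, None] * T[None, :]
        + rng.normal(0.0, cfg.clock_noise_sd, size=(len(clock_idx), n_samp)),
        0.0,
        1.0,
    )
    return values


TestKind = Literal["case_like", "control_like", "other_signature"]


def simulate_test_samples(
    sim: SimulatedCohort,
    kind: TestKind,
    n: int,
    seed: int,
    cohort_label: str | None = None,
) -> tuple[BetaMatrix, SampleSheet]:
    """Draw extra samples from the fitted generative state.

    ``case_like`` samples carry the planted signature (and the planted
    age acceleration), ``control_like`` carry neither, and
    ``other_signature`` samples carry the disjoint second signature —
    an epigenetically abnormal cohort that should still score low.
    """
    cfg = sim.config
    if kind == "other_signature" and cfg.n_other_signature_cpgs == 0:
        raise EpisigError("no other-signature CpGs were configured")
    if kind not in ("case_like", "control_like", "other_signature"):
        raise EpisigError(f"unknown test-sample kind {kind!r}")
    rng = np.random.default_rng(seed)
    label = cohort_label or kind

    ages = rng.uniform(*cfg.age_range_control, size=n)
    if kind == "case_like":
        accel = rng.normal(cfg.case_acceleration_years, cfg.case_acceleration_sd, n)
    else:
        accel = np.zeros(n)
    eff_age = np.maximum(
        ages + accel + rng.normal(0.0, cfg.clock_residual_sd, n), 0.05
    )
    props = rng.dirichlet(cfg.dirichlet_alpha, size=n)

    if kind == "case_like":
        shift = sim._case_shift
    elif kind == "other_signature":
        shift = sim._other_shift
    else:
        shift = np.zeros_like(sim._case_shift)

    probe_ids = list(sim.beta.probe_ids)
    roles = sim._probe_roles.to_numpy()
    deconv_idx = np.nonzero(roles == "deconv")[0]
    clock_idx = np.nonzero(roles == "clock")[0]
    values = _generate_betas(
        rng,
        cfg,
        base_logit=sim._baseline_logit,
        shifts=np.tile(shift[:, None], (1, n)),
        loadings=sim._cell_loadings,
        props=props,
        ref=sim.cell_reference,
        deconv_idx=deconv_idx,
        clock_idx=clock_idx,
        clock_mu=sim._clock_mu,
        clock_slope=sim._clock_slope,
        eff_age=eff_age,
    )
    ids = [f"{label.upper()}{j + 1:03d}" for j in range(n)]
    beta = BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=ids))
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ids,
                "group": "case" if kind == "case_like" else "control",
                "role": "test",
                "sex": rng.permuted(np.array((["F", "M"] * n)[:n], dtype=object)),
                "age_years": np.round(ages, 2),
                "cohort": label,
            }
        )
    )
    return beta, sheet


def make_degenerate_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write small edge-case fixtures exercising error and boundary paths.

    Emits: a beta matrix with an all-zero probe and missing cells, a
    single-sex sample sheet, a matrix with a duplicated feature row, a
    manifest with a gene exactly 10 kb from its probe, and an n = 1
    sample sheet.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    beta = BetaMatrix(
        pd.DataFrame(
            {
                "S1": [0.0, 0.5, 0.2, np.nan],
                "S2": [0.0, 0.6, 0.2, 0.7],
                "S3": [0.0, 0.4, np.nan, 0.8],
            },
            index=["cgZERO", "cgA", "cgB", "cgC"],
        )
    )
    paths["beta_edge"] = outdir / "beta_edge.tsv"
    write_beta_matrix(beta, paths["beta_edge"])

    single_sex = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3"],
                "group": ["case", "case", "control"],
                "role": ["discovery_case", "discovery_case", "discovery_control"],
                "sex": ["M", "M", "M"],
                "age_years": [5.0, 10.0, 7.0],
            }
        )
    )
    paths["single_sex_sheet"] = outdir / "single_sex_sheet.csv"
    single_sex.table.to_csv(paths["single_sex_sheet"], index=False)

    dup = BetaMatrix(
        pd.DataFrame(
            {
                "S1": [0.10, 0.10, 0.80],
                "S2": [0.30, 0.30, 0.55],
                "S3": [0.60, 0.60, 0.20],
                "S4": [0.85, 0.85, 0.40],
            },
            index=["cgDUP1", "cgDUP2", "cgOTHER"],
        )
    )
    paths["duplicate_features"] = outdir / "duplicate_features.tsv"
    write_beta_matrix(dup, paths["duplicate_features"])

    man = ProbeManifest(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [100_000, 200_000],
                "probe_class": ["cg", "cg"],
                "island_relation": ["Island", "OpenSea"],
                "snp_maf": [np.nan, np.nan],
                "cross_reactive": [False, False],
                # cgNEAR's gene starts exactly 10 kb downstream of the probe
                "genes": [
                    [GeneSpan("NEARGENE", 110_000, 115_000, "+")],
                    [GeneSpan("FARGENE", 250_000, 255_000, "+")],
                ],
            },
            index=pd.Index(["cgNEAR", "cgFAR"], name="probe_id"),
        )
    )
    paths["boundary_manifest"] = outdir / "boundary_manifest.tsv"
    write_manifest(man, paths["boundary_manifest"])

    n1 = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["ONLY1"],
                "group": ["case"],
                "role": ["test"],
                "sex": ["F"],
                "age_years": [7.0],
            }
        )
    )
    paths["n1_sheet"] = outdir / "n1_sheet.csv"
    n1.table.to_csv(paths["n1_sheet"], index=False)
    return paths
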