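"""Covariate-adjusted differential methylation and signature selection.

Per CpG, an ordinary least-squares model is fitted on the beta scale:

    beta_g ~ intercept + group + age + sex + cell proportions + clock residual

The group coefficient is the adjusted case effect. Residual variances
are shrunk toward a common prior by empirical Bayes: with per-probe
residual variance s_g^2 on d_g degrees of freedom and a scaled
inverse-chi-square prior (d0, s0^2), the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t-statistic t~ = coef / (s~_g * u_g) follows a
t-distribution on d0 + d_g degrees of freedom under the null (u_g is
the unscaled coefficient SD from the design). The hyperparameters
(d0, s0^2) are estimated by the method of moments on log s_g^2.

The signature is the set of CpGs passing a dual threshold: BH-adjusted
p (q) strictly below ``q_max`` and |delta beta| strictly above
``min_abs_delta``, where delta beta is the raw difference in group mean
beta. Enrichment of the signature in CpG islands/shores and in
user-supplied gene sets is assessed with one-sided hypergeometric
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .core_io import BetaMatrix, EpisigError, ProbeManifest, SampleSheet

# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def build_design(
    sheet: SampleSheet,
    cell_props: pd.DataFrame | None = None,
    residuals: pd.Series | None = None,
    include_covariates: bool = True,
) -> pd.DataFrame:
    """Build the per-sample design matrix for the differential model.

    Columns: intercept, group (case = 1, control = 0), age_years,
    sex (M = 1, F = 0), one column per supplied cell type, and the
    DNAm-age residual. With ``include_covariates=False`` only intercept
    and group are kept. Raises on rank deficiency, naming the columns
    responsible.
    """
    t = sheet.table
    idx = pd.Index(t["sample_id"])
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(t)),
        "group": (t["group"] == "case").to_numpy(dtype=float),
    }
    if include_covariates:
        cols["age_years"] = t["age_years"].to_numpy(dtype=float)
        cols["sex"] = (t["sex"] == "M").to_numpy(dtype=float)
        if cell_props is not None:
            cp = cell_props.reindex(idx)
            if cp.isna().any().any():
                raise EpisigError("cell proportions missing for some modeled samples")
            for ct in cp.columns:
                cols[str(ct)] = cp[ct].to_numpy(dtype=float)
        if residuals is not None:
            r = residuals.reindex(idx)
            if r.isna().any():
                raise EpisigError("DNAm-age residual missing for some modeled samples")
            cols["dnam_age_residual"] = r.to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=idx)
    _check_full_rank(design)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        constant = [
            c for c in design.columns if c != "intercept" and design[c].nunique() == 1
        ]
        if constant:
            raise EpisigError(f"design matrix rank-deficient: constant columns {constant}")
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, pivoting=True)
        tol = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [design.columns[piv[i]] for i in range(X.shape[1]) if abs(R[i, i]) <= tol]
        raise EpisigError(f"design matrix rank-deficient: collinear columns {bad}")


# ---------------------------------------------------------------------------
# Per-probe linear fits
# ---------------------------------------------------------------------------


def fit_linear_models(
    beta: BetaMatrix, design: pd.DataFrame, coef_name: str = "group"
) -> pd.DataFrame:
    """Per-CpG OLS of beta on the design; extract the group coefficient.

    Returns a DataFrame indexed by probe with columns ``coef`` (group
    effect on the beta scale), ``sigma`` (residual SD), ``df_residual``
    and ``unscaled_sd`` (sqrt of the group diagonal of (X'X)^-1).
    Probes with missing values are fitted on complete cases with
    correspondingly fewer residual degrees of freedom; probes whose
    complete-case design is rank-deficient or leaves df <= 0 get NaN
    statistics and are excluded from moderation.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if beta.shape[1] != n:
        raise EpisigError("beta matrix and design have different sample counts")
    if list(design.index) != list(beta.sample_ids):
        raise EpisigError("design rows are not aligned to beta matrix columns")
    if n <= p:
        raise EpisigError(f"need more samples ({n}) than design columns ({p})")
    g = list(design.columns).index(coef_name)
    Y = beta.values.to_numpy(dtype=float)

    xtx_inv = np.linalg.inv(X.T @ X)
    u_full = float(np.sqrt(xtx_inv[g, g]))
    hat = xtx_inv @ X.T

    coef = np.full(Y.shape[0], np.nan)
    sigma = np.full(Y.shape[0], np.nan)
    dfres = np.zeros(Y.shape[0])
    unscaled = np.full(Y.shape[0], np.nan)

    complete = ~np.isnan(Y).any(axis=1)
    if complete.any():
        B = hat @ Y[complete].T  # p x n_probes
        resid = Y[complete].T - X @ B
        rss = np.sum(resid**2, axis=0)
        coef[complete] = B[g]
        dfres[complete] = n - p
        sigma[complete] = np.sqrt(rss / (n - p))
        unscaled[complete] = u_full

    for i in np.nonzero(~complete)[0]:
        y = Y[i]
        ok = ~np.isnan(y)
        Xi = X[ok]
        if ok.sum() <= p or np.linalg.matrix_rank(Xi) < p:
            continue  # left NaN: flagged, excluded from moderation
        xtxi = np.linalg.inv(Xi.T @ Xi)
        b = xtxi @ Xi.T @ y[ok]
        r = y[ok] - Xi @ b
        df_i = ok.sum() - p
        coef[i] = b[g]
        dfres[i] = df_i
        sigma[i] = np.sqrt(np.sum(r**2) / df_i)
        unscaled[i] = np.sqrt(xtxi[g, g])

    return pd.DataFrame(
        {"coef": coef, "sigma": sigma, "df_residual": dfres, "unscaled_sd": unscaled},
        index=beta.probe_ids,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModerationParams:
    """Scaled inverse-chi-square prior on residual variances."""

    d0: float  # prior degrees of freedom; may be +inf
    s0_sq: float  # prior variance


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def estimate_prior(sigmas: np.ndarray, dfs: np.ndarray) -> ModerationParams:
    """Method-of-moments fit of (d0, s0^2) on log residual variances.

    Probes with zero or non-finite variance (or df <= 0) are excluded
    from hyperparameter estimation. When the observed log-variance
    spread is no wider than sampling noise alone, d0 is +infinity and
    every posterior variance equals s0^2.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    dfs = np.asarray(dfs, dtype=float)
    ok = np.isfinite(sigmas) & (sigmas > 0) & (dfs > 0)
    if ok.sum() < 10:
        raise EpisigError("need >= 10 probes with positive residual variance")
    s2 = sigmas[ok] ** 2
    d = dfs[ok]
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1) - np.mean(polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderate_variances(
    fits: pd.DataFrame, prior_df: float | None = None
) -> tuple[ModerationParams, pd.DataFrame]:
    """Compute moderated t-statistics and two-sided p-values.

    ``prior_df`` overrides the estimated prior degrees of freedom:
    0 disables moderation (ordinary t on d_g df), +inf pools every
    probe to the prior variance, None (default) estimates d0 from the
    data. Returns the prior and a copy of ``fits`` with ``moderated_t``
    and ``p`` columns; probes with NaN fits stay NaN.
    """
    sig = fits["sigma"].to_numpy(dtype=float)
    dfs = fits["df_residual"].to_numpy(dtype=float)
    if not np.any(np.isfinite(sig) & (sig > 0)):
        raise EpisigError("all residual variances are zero; cannot moderate")
    params = estimate_prior(sig, dfs)
    if prior_df is not None:
        params = ModerationParams(d0=float(prior_df), s0_sq=params.s0_sq)

    coef = fits["coef"].to_numpy(dtype=float)
    u = fits["unscaled_sd"].to_numpy(dtype=float)
    ok = np.isfinite(sig) & (dfs > 0) & np.isfinite(coef)

    d0 = params.d0
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(sig, params.s0_sq)
            df_total = np.full_like(dfs, np.inf)
        else:
            s2_post = (d0 * params.s0_sq + dfs * sig**2) / (d0 + dfs)
            df_total = d0 + dfs
        tstat = coef / (np.sqrt(s2_post) * u)
    tstat[~ok] = np.nan
    pvals = np.full_like(tstat, np.nan)
    finite = ok & np.isfinite(tstat)
    inf_df = finite & np.isinf(df_total)
    pvals[inf_df] = 2.0 * stats.norm.sf(np.abs(tstat[inf_df]))
    reg = finite & ~np.isinf(df_total)
    pvals[reg] = 2.0 * stats.t.sf(np.abs(tstat[reg]), df_total[reg])

    out = fits.copy()
    out["moderated_t"] = tstat
    out["p"] = pvals
    return params, out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise EpisigError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Effect sizes, selection, direction
# ---------------------------------------------------------------------------


def delta_beta(beta: BetaMatrix, sheet: SampleSheet) -> pd.Series:
    """Difference in group mean beta (case - control), skipping missing.

    Computed over the discovery samples in ``sheet``. A probe missing
    in an entire group gets NaN with a warning.
    """
    disc = sheet.discovery()
    if len(disc.table) == 0:
        disc = sheet
    case_ids = [
        s for s, g in zip(disc.sample_ids, disc.table["group"]) if g == "case"
    ]
    ctrl_ids = [
        s for s, g in zip(disc.sample_ids, disc.table["group"]) if g == "control"
    ]
    if not case_ids or not ctrl_ids:
        raise EpisigError("both groups must be nonempty for delta beta")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        case_mean = np.nanmean(
            beta.values[case_ids].to_numpy(dtype=float), axis=1
        )
        ctrl_mean = np.nanmean(
            beta.values[ctrl_ids].to_numpy(dtype=float), axis=1
        )
    db = case_mean - ctrl_mean
    n_bad = int(np.isnan(db).sum())
    if n_bad:
        warnings.warn(f"{n_bad} probes missing in an entire group; delta beta NaN")
    return pd.Series(db, index=beta.probe_ids, name="delta_beta")


@dataclass
class DiffMethResult:
    """Per-CpG differential methylation table plus the moderation prior.

    ``table`` columns: coef, delta_beta, sigma, df_residual,
    moderated_t, p, q, direction.
    """

    table: pd.DataFrame
    params: ModerationParams
    flagged_probes: list[str] = field(default_factory=list)


def run_differential(
    beta: BetaMatrix,
    sheet: SampleSheet,
    design: pd.DataFrame,
    prior_df: float | None = None,
) -> DiffMethResult:
    """Fit, moderate, BH-adjust and annotate direction for every probe.

    Probes that cannot be fitted (zero df, rank-deficient complete
    cases, or an empty group for delta beta) are dropped from the table
    and listed in ``flagged_probes``.
    """
    fits = fit_linear_models(beta, design)
    params, moderated = moderate_variances(fits, prior_df=prior_df)
    db = delta_beta(beta, sheet)
    moderated["delta_beta"] = db
    ok = moderated["p"].notna() & moderated["delta_beta"].notna()
    flagged = list(moderated.index[~ok])
    table = moderated.loc[ok].copy()
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["direction"] = np.where(table["delta_beta"] > 0, "hyper", "hypo")
    table = table[
        ["coef", "delta_beta", "sigma", "df_residual", "unscaled_sd",
         "moderated_t", "p", "q", "direction"]
    ]
    return DiffMethResult(table=table, params=params, flagged_probes=flagged)


def select_signature(
    result: DiffMethResult, q_max: float = 0.05, min_abs_delta: float = 0.10
) -> list[str]:
    """Signature CpGs: q < q_max AND |delta beta| > min_abs_delta (strict).

    Sorted by q ascending, then |delta beta| descending, then probe id.
    """
    t = result.table
    mask = (t["q"] < q_max) & (t["delta_beta"].abs() > min_abs_delta)
    sel = t.loc[mask].copy()
    if sel.empty:
        warnings.warn("empty signature at the given thresholds")
        return []
    sel["_absdb"] = sel["delta_beta"].abs()
    sel["_pid"] = sel.index  # deterministic tie-break within equal (q, |dbeta|)
    sel = sel.sort_values(
        by=["q", "_absdb", "_pid"], ascending=[True, False, True], kind="mergesort"
    )
    return list(sel.index)


def direction_summary(result: DiffMethResult, signature: list[str]) -> tuple[float, float]:
    """Fractions of hyper- and hypomethylated CpGs in the signature."""
    if not signature:
        raise EpisigError("direction summary of an empty signature")
    d = result.table.loc[signature, "direction"]
    frac_hyper = float((d == "hyper").mean())
    return frac_hyper, 1.0 - frac_hyper


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentRecord:
    """One hypergeometric enrichment test result."""

    term: str
    N: int  # background size
    K: int  # background hits
    n: int  # foreground size
    k: int  # foreground hits
    p: float
    q: float | None = None
    gene_hits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise EpisigError("enrichment counts inconsistent (k > min(K, n))")


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric P(X >= k)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def island_shore_enrichment(
    signature: list[str], manifest: ProbeManifest, background: list[str]
) -> EnrichmentRecord:
    """Test whether the signature over-represents CpG islands and shores.

    Foreground is the signature, background the post-QC probe set;
    a probe is a hit when its island relation is Island or Shore.
    """
    bg = set(background)
    missing = [p for p in signature if p not in bg]
    if missing:
        raise EpisigError(f"signature probes not in background: {missing[:5]}")
    ann = manifest.require(background)
    hit = ann["island_relation"].isin(["Island", "Shore"])
    hits = set(ann.index[hit])
    N, K, n = len(bg), len(hits), len(signature)
    k = sum(1 for p in signature if p in hits)
    return EnrichmentRecord(
        term="Island|Shore", N=N, K=K, n=n, k=k, p=hypergeom_upper(N, K, n, k)
    )


@dataclass
class GeneMapping:
    """CpG-to-gene assignment within a distance cutoff."""

    per_cpg: dict[str, list[str]]
    max_distance: int

    @property
    def genes(self) -> list[str]:
        return sorted({g for gl in self.per_cpg.values() for g in gl})

    @property
    def multi_hit_genes(self) -> list[str]:
        counts: dict[str, int] = {}
        for gl in self.per_cpg.values():
            for g in set(gl):
                counts[g] = counts.get(g, 0) + 1
        return sorted(g for g, c in counts.items() if c >= 2)


def map_cpgs_to_genes(
    probes: list[str], manifest: ProbeManifest, max_distance: int = 10_000
) -> GeneMapping:
    """Map each CpG to every gene span within ``max_distance`` bp.

    Distance is measured from the probe position to the nearest edge of
    the annotated span (0 inside the span); the cutoff is inclusive.
    """
    ann = manifest.require(probes)
    per_cpg: dict[str, list[str]] = {}
    for probe in probes:
        pos = int(ann.loc[probe, "pos"])
        hits = []
        for gene in ann.loc[probe, "genes"]:
            if gene.start <= pos <= gene.end:
                dist = 0
            else:
                dist = min(abs(pos - gene.start), abs(pos - gene.end))
            if dist <= max_distance:
                hits.append(gene.symbol)
        per_cpg[probe] = sorted(set(hits))
    return GeneMapping(per_cpg=per_cpg, max_distance=max_distance)


def geneset_enrichment(
    foreground_genes,
    gene_sets: dict[str, set[str]],
    background_genes,
    min_hits: int = 3,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment over genes, BH across terms.

    Returns a DataFrame (one row per term, sorted by p) with counts,
    p, q, the hit list, and a ``reported`` flag marking terms with at
    least ``min_hits`` gene hits and q below ``q_max``.
    """
    if not gene_sets:
        raise EpisigError("no gene sets supplied")
    bg = set(background_genes)
    if not bg:
        raise EpisigError("empty background gene universe")
    fg = set(foreground_genes) & bg
    rows = []
    for term in sorted(gene_sets):
        members = set(gene_sets[term]) & bg
        hits = sorted(fg & members)
        p = hypergeom_upper(len(bg), len(members), len(fg), len(hits))
        rows.append(
            {
                "term": term,
                "N": len(bg),
                "K": len(members),
                "n": len(fg),
                "k": len(hits),
                "p": p,
                "gene_hits": ";".join(hits),
            }
        )
    df = pd.DataFrame(rows).set_index("term")
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["reported"] = (df["k"] >= min_hits) & (df["q"] < q_max)
    return df.sort_values(["p", "k"], ascending=[True, False], kind="mergesort")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (term, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise EpisigError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_diffmeth(result: DiffMethResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index_label="probe_id")
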