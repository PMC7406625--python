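"""Ridge-regression genome scan over bins and downstream QTL statistics.

Bin predictors in a substitution-line panel are strongly collinear
(adjacent bins differ by a handful of recombinants), so the genome scan
fits **all bins jointly under an L2 penalty** instead of marker-by-marker
regression. Per-bin significance comes from pointwise permutation of the
trait: the standardized ridge coefficients are recomputed for permuted
trait vectors (the cross-validated penalty held fixed) and the p-value of
bin *j* is the rank of its observed |coefficient| among the permuted ones.
An analytic ridge-t alternative is provided and labelled approximate.

Declared QTLs are maximal runs of adjacent bins below the significance
threshold, located at the lowest-p (peak) bin. Phenotypic variance
explained is decomposed over the declared peak bins with the LMG method
(average over all predictor orderings of the sequential R-squared
increment) on an ordinary-least-squares refit. Cross-trait clustering of
QTLs whose significant spans overlap yields seed-dormancy regions, and
single-marker / two-locus statistics cover F2 validation and epistasis.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._rng import substream
from .binmap import BinMap

log = logging.getLogger("dormqtl")


@dataclass(frozen=True)
class ScanConfig:
    """Genome-scan settings (defaults follow the motivating study)."""

    alpha: float = 0.005
    n_permutations: int = 2000
    penalty: str | float = "cv"  # 'cv' or a fixed ridge penalty
    p_method: str = "permutation"  # or 'ridge-t' (approximate)
    seed: int = 0
    max_exact_lmg_predictors: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.p_method == "permutation" and self.n_permutations < 100:
            raise ValueError("need >= 100 permutations for permutation p-values")


def _kfold_ridge_lambda(Xs: np.ndarray, yc: np.ndarray, alphas: np.ndarray,
                        k: int = 5, seed: int = 0) -> float:
    """Ridge penalty minimizing k-fold CV error, via one SVD per fold.

    A single thin SVD of each training block makes every candidate penalty
    a diagonal reweighting, so the grid costs k SVDs regardless of its size.
    """
    n = len(yc)
    idx = substream(seed, "ridge-cv").permutation(n)
    folds = np.array_split(idx, k)
    err = np.zeros(len(alphas))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        U, s, Vt = np.linalg.svd(Xs[mask], full_matrices=False)
        uy = U.T @ yc[mask]
        XvV = Xs[fold] @ Vt.T
        for a, lam in enumerate(alphas):
            pred = XvV @ (s / (s ** 2 + lam) * uy)
            err[a] += float(((yc[fold] - pred) ** 2).sum())
    return float(alphas[int(np.argmin(err))])


class RidgeQTLScanner(BaseEstimator):
    """Joint ridge fit of all bins with permutation p-values per bin.

    Fitted attributes: ``coef_`` (standardized-predictor scale), ``signs_``
    (+1 = donor allele increases the trait), ``pvalues_``, ``lambda_``.
    """

    def __init__(self, alpha: float = 0.005, n_permutations: int = 2000,
                 penalty: str | float = "cv", p_method: str = "permutation",
                 random_state: int = 0, min_lines: int = 30):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.penalty = penalty
        self.p_method = p_method
        self.random_state = random_state
        self.min_lines = min_lines

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n_lines, n_bins) aligned with y")
        keep = np.isfinite(y)
        X, y = X[keep], y[keep]
        n, p = X.shape
        if n < self.min_lines:
            raise ValueError(f"need >= {self.min_lines} lines with a trait value, got {n}")
        if np.ptp(y) == 0:
            raise ValueError("constant trait")
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance bins must be dropped before scanning "
                             "(see BinGenotypes.to_numeric)")
        Xs = (X - X.mean(axis=0)) / sd
        yc = y - y.mean()

        if self.penalty == "cv":
            # 5-fold CV; leave-one-out/GCV is pathological when n_bins > n_lines
            # (interpolation regime favours a vanishing penalty)
            lam = _kfold_ridge_lambda(Xs, yc, np.logspace(-2, 5, 40),
                                      k=5, seed=self.random_state)
        else:
            lam = float(self.penalty)
        self.lambda_ = lam

        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        shrink = s / (s ** 2 + lam)
        coef = Vt.T @ (shrink * (U.T @ yc))
        self.coef_ = coef
        self.signs_ = np.where(coef >= 0, 1, -1)
        # marginal association per bin (|correlation| * const): the ridge
        # coefficient decides significance jointly, but under shrinkage it
        # apportions signal among collinear bins arbitrarily, so peak
        # *localization* within a tied run uses the marginal statistic
        self.marginal_stat_ = np.abs(Xs.T @ yc) / len(yc)

        if self.p_method == "permutation":
            if self.n_permutations < 100:
                raise ValueError("need >= 100 permutations")
            rng = substream(self.random_state, "ridge-scan")
            B = self.n_permutations
            Yp = np.empty((n, B))
            for b in range(B):
                Yp[:, b] = rng.permutation(yc)
            C = Vt.T @ (shrink[:, None] * (U.T @ Yp))
            exceed = (np.abs(C) >= np.abs(coef)[:, None]).sum(axis=1)
            self.pvalues_ = (1.0 + exceed) / (B + 1.0)
        elif self.p_method == "ridge-t":
            # approximate: normal-theory SEs at the fixed penalty
            fitted = U @ (shrink * s * (U.T @ yc))
            df_eff = float(np.sum(s ** 2 / (s ** 2 + lam)))
            sigma2 = float(np.sum((yc - fitted) ** 2)) / max(n - df_eff, 1.0)
            var = sigma2 * np.einsum("ji,j,ji->i", Vt, shrink ** 2, Vt)
            t = coef / np.sqrt(np.maximum(var, 1e-300))
            self.pvalues_ = 2.0 * stats.t.sf(np.abs(t), df=max(n - df_eff, 1.0))
        else:
            raise ValueError(f"unknown p_method {self.p_method!r}")
        self.n_lines_ = n
        return self


def ridge_scan(X: np.ndarray, y: np.ndarray, cfg: ScanConfig = ScanConfig()
               ) -> tuple[np.ndarray, np.ndarray]:
    """Functional facade: returns (p-values, coefficient signs) per bin."""
    sc = RidgeQTLScanner(alpha=cfg.alpha, n_permutations=cfg.n_permutations,
                         penalty=cfg.penalty, p_method=cfg.p_method,
                         random_state=cfg.seed).fit(X, y)
    return sc.pvalues_, sc.signs_


# ---------------------------------------------------------------------------
# QTL declaration
# ---------------------------------------------------------------------------

@dataclass
class QTLRecord:
    trait: str
    name: str
    chrom: str
    peak_bin_id: str
    peak_bin_index: int  # genome-order index into the bin map
    peak_start: int
    peak_end: int
    pvalue: float
    sign: int  # +1: donor allele increases the trait
    span_start: int  # contiguous significant run, bp
    span_end: int
    n_span_bins: int
    pve: float | None = None


def _chrom_number(chrom: str) -> str:
    digits = re.sub(r"\D", "", chrom)
    return digits or chrom


def declare_qtls(pvalues: np.ndarray, signs: np.ndarray, bin_map: BinMap,
                 trait: str, alpha: float = 0.005,
                 stats: np.ndarray | None = None) -> list[QTLRecord]:
    """Collapse runs of adjacent significant bins into located QTLs.

    ``pvalues``/``signs`` are aligned to the full bin map (NaN for bins that
    were dropped from the fit; NaN breaks adjacency). Each maximal run of
    adjacent bins with p < alpha yields one record at its lowest-p bin.
    Permutation p-values are discrete and floor at 1/(B+1), so strong bins
    tie; ties are broken by the larger |standardized coefficient| when
    ``stats`` is given, then toward the lower genomic coordinate. Names are
    ``q<trait><chrom>.<serial>`` with serials ordered by position within
    each chromosome.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) != bin_map.n_bins:
        raise ValueError("p-values not aligned to the bin map")
    if stats is not None and len(stats) != bin_map.n_bins:
        raise ValueError("stats not aligned to the bin map")
    bins = bin_map.bins
    records: list[QTLRecord] = []
    sig = np.where(np.isnan(pvalues), False, pvalues < alpha)
    for chrom in dict.fromkeys(bins["chrom"]):
        idx = np.flatnonzero((bins["chrom"] == chrom).to_numpy())
        runs: list[list[int]] = []
        for j in idx:
            if sig[j]:
                if runs and runs[-1][-1] == j - 1:
                    runs[-1].append(j)
                else:
                    runs.append([j])
        for serial, run in enumerate(runs, start=1):
            run_p = pvalues[run]
            best = np.flatnonzero(run_p == run_p.min())
            if stats is not None and len(best) > 1:
                tied_stats = np.asarray(stats, dtype=float)[np.asarray(run)[best]]
                best = best[tied_stats == tied_stats.max()]
            peak = run[int(best[0])]  # remaining ties -> lower coordinate
            records.append(QTLRecord(
                trait=trait,
                name=f"q{trait}{_chrom_number(chrom)}.{serial}",
                chrom=chrom,
                peak_bin_id=bins["bin_id"].iat[peak],
                peak_bin_index=int(peak),
                peak_start=int(bins["start"].iat[peak]),
                peak_end=int(bins["end"].iat[peak]),
                pvalue=float(pvalues[peak]),
                sign=int(signs[peak]),
                span_start=int(bins["start"].iat[run[0]]),
                span_end=int(bins["end"].iat[run[-1]]),
                n_span_bins=len(run),
            ))
    return records


# ---------------------------------------------------------------------------
# LMG variance decomposition
# ---------------------------------------------------------------------------

def lmg_decomposition(X: np.ndarray, y: np.ndarray, exact_limit: int = 15,
                      n_orderings: int = 5000, seed: int = 0
                      ) -> tuple[np.ndarray, float, list[tuple[int, int]]]:
    """LMG relative importance: each predictor's average sequential R² gain.

    Averaging runs over all p! predictor orderings (computed exactly over
    subsets for p <= ``exact_limit``, else Monte-Carlo over orderings).
    Shares are non-negative and sum to the full OLS model R². Perfectly
    collinear duplicate predictors are merged onto their first occurrence
    (returned as (dropped, representative) pairs); merged predictors report
    the representative's share.

    Returns (shares aligned to input columns, full-model R², merges).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()

    # merge exact duplicates (|correlation| == 1 within numerical noise)
    norms = np.sqrt((Xc ** 2).sum(axis=0))
    if np.any(norms == 0):
        raise ValueError("constant predictor passed to LMG decomposition")
    R = (Xc / norms).T @ (Xc / norms)
    rep = list(range(p))
    merges: list[tuple[int, int]] = []
    for j in range(p):
        for k in range(j):
            if rep[k] == k and abs(R[j, k]) >= 1 - 1e-12:
                rep[j] = k
                merges.append((j, k))
                log.info("lmg: predictor %d perfectly collinear with %d; merged", j, k)
                break
    keep = [j for j in range(p) if rep[j] == j]
    Xk = Xc[:, keep]
    q = len(keep)

    sxx = Xk.T @ Xk
    sxy = Xk.T @ yc
    syy = float(yc @ yc)

    def r2_of(idx: tuple[int, ...]) -> float:
        if not idx:
            return 0.0
        a = np.asarray(idx)
        try:
            beta = np.linalg.solve(sxx[np.ix_(a, a)], sxy[a])
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(sxx[np.ix_(a, a)], sxy[a], rcond=None)[0]
        return float(beta @ sxy[a] / syy)

    shares_k = np.zeros(q)
    if q <= exact_limit:
        r2 = np.zeros(1 << q)
        for mask in range(1, 1 << q):
            r2[mask] = r2_of(tuple(j for j in range(q) if mask >> j & 1))
        fact = [math.factorial(k) for k in range(q + 1)]
        w = [fact[k] * fact[q - 1 - k] / fact[q] for k in range(q)]
        for j in range(q):
            bit = 1 << j
            acc = 0.0
            for mask in range(1 << q):
                if mask & bit:
                    continue
                acc += w[mask.bit_count()] * (r2[mask | bit] - r2[mask])
            shares_k[j] = acc
        full_r2 = float(r2[(1 << q) - 1])
    else:
        rng = substream(seed, "lmg-mc")
        order = np.arange(q)
        for _ in range(n_orderings):
            rng.shuffle(order)
            prev = 0.0
            chosen: list[int] = []
            for j in order:
                chosen.append(int(j))
                cur = r2_of(tuple(sorted(chosen)))
                shares_k[j] += cur - prev
                prev = cur
        shares_k /= n_orderings
        full_r2 = r2_of(tuple(range(q)))

    shares = np.zeros(p)
    pos = {j: i for i, j in enumerate(keep)}
    for j in range(p):
        shares[j] = shares_k[pos[rep[j]]]
    return shares, full_r2, merges


def assign_pve(records: list[QTLRecord], X_bins: np.ndarray, y: np.ndarray,
               exact_limit: int = 15, seed: int = 0) -> float:
    """Fill each record's PVE (%) from an LMG decomposition over the peak
    bins of all declared QTLs for the trait. Returns the full-model R²."""
    if not records:
        return 0.0
    shares, full_r2, _ = lmg_decomposition(X_bins, y, exact_limit, seed=seed)
    for rec, share in zip(records, shares):
        rec.pve = float(100.0 * share)
    return full_r2


# ---------------------------------------------------------------------------
# Cross-trait clustering into seed-dormancy regions
# ---------------------------------------------------------------------------

@dataclass
class SDRegion:
    """A genomic region where QTLs for several traits co-locate."""

    name: str
    chrom: str
    start: int
    end: int
    members: list[QTLRecord] = field(default_factory=list)
    n_traits: int = 0
    all_traits: bool = False


def cluster_sd_regions(records: list[QTLRecord], min_traits: int = 3,
                       n_traits_total: int = 4) -> list[SDRegion]:
    """Group QTLs from different traits whose significant spans overlap.

    Overlapping-span components supported by >= ``min_traits`` distinct
    traits become dormancy regions named ``qSD<chrom>.<serial>`` (serials
    by position within each chromosome); regions supported by every trait
    are flagged.
    """
    regions: list[SDRegion] = []
    chroms = list(dict.fromkeys(r.chrom for r in records))
    for chrom in chroms:
        recs = sorted((r for r in records if r.chrom == chrom),
                      key=lambda r: (r.span_start, r.span_end))
        components: list[list[QTLRecord]] = []
        cur: list[QTLRecord] = []
        cur_end = -1
        for r in recs:
            if not cur or r.span_start < cur_end:
                cur.append(r)
                cur_end = max(cur_end, r.span_end)
            else:
                components.append(cur)
                cur, cur_end = [r], r.span_end
        if cur:
            components.append(cur)
        serial = 0
        for comp in components:
            traits = {r.trait for r in comp}
            if len(traits) < min_traits:
                continue
            serial += 1
            regions.append(SDRegion(
                name=f"qSD{_chrom_number(chrom)}.{serial}",
                chrom=chrom,
                start=min(r.span_start for r in comp),
                end=max(r.span_end for r in comp),
                members=comp,
                n_traits=len(traits),
                all_traits=len(traits) >= n_traits_total,
            ))
    return regions


# ---------------------------------------------------------------------------
# F2 single-marker analysis
# ---------------------------------------------------------------------------

@dataclass
class F2Result:
    marker: str
    additive: float | None  # a = (mean(AA) - mean(BB)) / 2, AA = donor hom
    dominance: float | None  # d = mean(AB) - midparent
    pvalue: float
    pve: float  # %
    lod: float
    class_means: dict = field(default_factory=dict)
    class_n: dict = field(default_factory=dict)


def f2_single_marker(genotypes, trait, marker: str = "") -> F2Result:
    """Additive/dominance effects and one-way ANOVA at one codominant marker.

    ``genotypes`` are per-individual classes 'AA' (donor hom), 'AB', 'BB'.
    PVE is the between-class share of the total sum of squares;
    LOD = (n/2) * log10(SS_total / SS_residual).
    """
    g = np.asarray(genotypes)
    y = np.asarray(trait, dtype=float)
    classes = [c for c in ("AA", "AB", "BB") if np.any(g == c)]
    if len(classes) < 2:
        raise ValueError("need at least two genotype classes")
    groups = {c: y[g == c] for c in classes}
    means = {c: float(v.mean()) for c, v in groups.items()}
    ns = {c: int(len(v)) for c, v in groups.items()}

    a = (means["AA"] - means["BB"]) / 2 if {"AA", "BB"} <= set(classes) else None
    d = (means["AB"] - (means["AA"] + means["BB"]) / 2
         if {"AA", "AB", "BB"} <= set(classes) else None)

    n = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_between = float(sum(ns[c] * (means[c] - grand) ** 2 for c in classes))
    ss_resid = ss_total - ss_between
    pve = 100.0 * ss_between / ss_total if ss_total > 0 else 0.0
    if ss_resid <= 0:
        pvalue, lod = 0.0, float("inf")
    else:
        pvalue = float(stats.f_oneway(*groups.values()).pvalue)
        lod = (n / 2.0) * math.log10(ss_total / ss_resid)
    return F2Result(marker, a, d, pvalue, pve, lod, means, ns)


# ---------------------------------------------------------------------------
# Two-locus epistasis ANOVA
# ---------------------------------------------------------------------------

@dataclass
class EpistasisTable:
    cell_stats: pd.DataFrame  # per two-locus class: n and trait mean
    anova: pd.DataFrame       # locus1, locus2, interaction, residual rows
    n: int
    n_cells: int
    note: str = ""


def epistasis_anova(geno1, geno2, trait) -> EpistasisTable:
    """Two-way fixed-effects ANOVA with interaction on two-locus classes.

    Genotypes are 'AA'/'AB'/'BB' per locus (up to 9 classes). Unbalanced
    data — inherent to F2 ratios — are handled with Type-II sums of
    squares; empty cells reduce the interaction degrees of freedom, which
    is noted in the output.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"g1": np.asarray(geno1), "g2": np.asarray(geno2),
                       "y": np.asarray(trait, dtype=float)})
    for col in ("g1", "g2"):
        if df[col].nunique() < 2:
            raise ValueError(f"locus {col} has fewer than two genotype classes")
    cells = (df.groupby(["g1", "g2"], sort=True)["y"]
               .agg(n="count", mean="mean").reset_index())
    n_cells = len(cells)
    model = ols("y ~ C(g1) + C(g2) + C(g1):C(g2)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={
        "C(g1)": "locus1", "C(g2)": "locus2",
        "C(g1):C(g2)": "interaction", "Residual": "residual",
    })
    note = ""
    full_int_df = (df["g1"].nunique() - 1) * (df["g2"].nunique() - 1)
    if n_cells < df["g1"].nunique() * df["g2"].nunique():
        note = (f"{n_cells} of {df['g1'].nunique() * df['g2'].nunique()} two-locus "
                f"classes observed; interaction df reduced from {full_int_df} to "
                f"{int(table.loc['interaction', 'df'])}")
        log.info("epistasis_anova: %s", note)
    return EpistasisTable(cells, table, len(df), n_cells, note)


def calls_to_f2_classes(calls: np.ndarray) -> np.ndarray:
    """Map SNPMatrix codes A/H/B to F2 classes AA/AB/BB ('-' -> '')."""
    lut = {"A": "AA", "H": "AB", "B": "BB", "-": ""}
    return np.array([lut[c] for c in calls])
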