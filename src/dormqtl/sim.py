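"""Synthetic CSSL / BIL / F2 populations with planted germination QTLs.

No genotype or phenotype data are distributed with this package, so every
analysis stage is exercised on simulated populations whose ground truth is
known. The simulator emulates the two study designs:

* **BIL** — a donor x recurrent F1 backcrossed once to the recurrent parent,
  then advanced by single-seed descent for a configurable number of selfing
  generations (default 7, i.e. BC1F1 -> F8). Expected donor allele frequency
  is 1/4 per marker; residual heterozygosity halves per selfing generation.
* **CSSL** — lines carrying one to a few homozygous donor segments on an
  otherwise recurrent background. The breeding scheme is not re-enacted
  marker-by-marker; candidates are produced by repeated backcrossing of the
  introgressed haplotype followed by fixation, then greedily selected to
  tile the genome (the endpoint property of marker-assisted CSSL panels).
* **F2** — one selfing of the F1, for single-marker validation and
  two-locus epistasis analyses.

Meiosis uses the Haldane model (no interference): crossover counts are
Poisson with mean map-length/100 cM and positions uniform in cM. Physical
to genetic scaling defaults to 270 kb/cM (rice-typical) and is configurable.

Germination phenotypes come from a latent logistic curve per line,
``G(t) = Gmax * sigmoid((t - t50)/slope)``: each of ``n_seeds`` seeds
germinates with probability Gmax at a logistic(t50, slope) time, otherwise
never. Planted QTLs shift Gmax / t50 / slope additively by donor-allele
dosage (recurrent hom 0, het a+d, donor hom 2a), optionally with an
additive-by-additive epistatic term on centered dosages. Because effects act
on curve parameters rather than on individual traits, the four derived
traits (G3d, G7d, T50, AUC) inherit a realistic correlation structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .io import SNPMatrix

log = logging.getLogger("dormqtl")

# ancestry labels on a haplotype / diplotype
REC, DONOR = 0, 1  # haplotype labels; diploid labels are dosages 0/1/2


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Chromosome sizes and marker positions with a linear bp<->cM scaling."""

    chrom_ids: tuple[str, ...]
    lengths_bp: dict[str, int]
    marker_positions: dict[str, np.ndarray]  # 1-based bp, strictly increasing
    kb_per_cm: float = 270.0

    def __post_init__(self) -> None:
        for chrom in self.chrom_ids:
            pos = self.marker_positions[chrom]
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
            if len(pos) and (pos[0] < 1 or pos[-1] > self.lengths_bp[chrom]):
                raise ValueError(f"marker positions outside chromosome {chrom}")

    def length_cm(self, chrom: str) -> float:
        return self.lengths_bp[chrom] / (self.kb_per_cm * 1000.0)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths_bp.values())

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.marker_positions.values())

    def marker_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_ids:
            for p in self.marker_positions[chrom]:
                rows.append((chrom, int(p), f"{chrom}_{int(p)}"))
        return pd.DataFrame(rows, columns=["chrom", "pos", "marker_id"])

    @classmethod
    def regular(cls, n_chrom: int = 5, markers_per_chrom: int = 120,
                spacing_bp: int = 270_000, kb_per_cm: float = 270.0) -> "GeneticMap":
        """Evenly spaced markers; chromosome length = markers x spacing."""
        chrom_ids = tuple(f"chr{i + 1}" for i in range(n_chrom))
        lengths = {c: spacing_bp * markers_per_chrom for c in chrom_ids}
        positions = {
            c: spacing_bp * np.arange(markers_per_chrom, dtype=np.int64) + spacing_bp // 2
            for c in chrom_ids
        }
        return cls(chrom_ids, lengths, positions, kb_per_cm)


def haldane_rec_frac(d_cm) -> float | np.ndarray:
    """Haldane map function: r = (1 - exp(-2d/100)) / 2 for d in cM."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


# ---------------------------------------------------------------------------
# Haplotypes and meiosis
#
# A chromosome haplotype is (ends, labels): segment i covers
# [ends[i-1], ends[i]) in bp (ends[-1] == chromosome length), with ancestry
# labels[i] in {REC, DONOR}. A whole-genome haplotype is a dict chrom -> that.
# ---------------------------------------------------------------------------

Seg = tuple[np.ndarray, np.ndarray]


def _const_hap(gmap: GeneticMap, label: int) -> dict[str, Seg]:
    return {
        c: (np.array([gmap.lengths_bp[c]], dtype=np.int64), np.array([label], dtype=np.int8))
        for c in gmap.chrom_ids
    }


def _merge_runs(ends: list[int], labels: list[int]) -> Seg:
    out_e, out_l = [], []
    for e, l in zip(ends, labels):
        if out_l and out_l[-1] == l:
            out_e[-1] = e
        else:
            out_e.append(e)
            out_l.append(l)
    return np.array(out_e, dtype=np.int64), np.array(out_l, dtype=np.int8)


def _slice_hap(hap: Seg, lo: int, hi: int) -> tuple[list[int], list[int]]:
    """Segments of ``hap`` restricted to [lo, hi), as (ends, labels) lists."""
    ends, labels = hap
    i = int(np.searchsorted(ends, lo, side="right"))
    out_e, out_l = [], []
    while i < len(ends):
        e = int(min(ends[i], hi))
        out_e.append(e)
        out_l.append(int(labels[i]))
        if ends[i] >= hi:
            break
        i += 1
    return out_e, out_l


def _meiosis_chrom(h1: Seg, h2: Seg, length_bp: int, length_cm: float,
                   kb_per_cm: float, rng: np.random.Generator) -> Seg:
    """One recombinant gamete chromosome under the Haldane model."""
    n_co = rng.poisson(length_cm / 100.0)
    cuts_cm = np.sort(rng.uniform(0.0, length_cm, size=n_co))
    cuts = np.unique((cuts_cm * kb_per_cm * 1000.0).astype(np.int64))
    cuts = cuts[(cuts > 0) & (cuts < length_bp)]
    cur = int(rng.integers(2))
    bounds = [0, *cuts.tolist(), length_bp]
    out_e: list[int] = []
    out_l: list[int] = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        src = h1 if (cur + k) % 2 == 0 else h2
        e, l = _slice_hap(src, lo, hi)
        out_e.extend(e)
        out_l.extend(l)
    return _merge_runs(out_e, out_l)


def simulate_gamete(diplotype: tuple[dict[str, Seg], dict[str, Seg]],
                    gmap: GeneticMap, rng: np.random.Generator) -> dict[str, Seg]:
    """Draw one gamete from a diploid parent over the whole map."""
    h1, h2 = diplotype
    if not gmap.chrom_ids:
        raise ValueError("empty genetic map")
    return {
        c: _meiosis_chrom(h1[c], h2[c], gmap.lengths_bp[c], gmap.length_cm(c),
                          gmap.kb_per_cm, rng)
        for c in gmap.chrom_ids
    }


def _diploid_mosaic(h1: Seg, h2: Seg) -> Seg:
    """Combine two haplotypes into a dosage mosaic (labels 0/1/2)."""
    ends = np.union1d(h1[0], h2[0])
    l1 = h1[1][np.searchsorted(h1[0], ends, side="left")]
    l2 = h2[1][np.searchsorted(h2[0], ends, side="left")]
    return _merge_runs(ends.tolist(), (l1.astype(np.int16) + l2).tolist())


def _ancestry_at(mosaic: Seg, positions: np.ndarray) -> np.ndarray:
    """Dosage labels at 1-based bp positions (position p lies in [p-1, p))."""
    ends, labels = mosaic
    return labels[np.searchsorted(ends, positions - 1, side="right")]


_CALL = np.array(["B", "H", "A"], dtype="<U1")  # dosage 0/1/2 -> call


# ---------------------------------------------------------------------------
# Specs and truth
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Configuration of one simulated mapping population."""

    design: str  # CSSL | BIL | F2
    n_lines: int
    seed: int = 0
    selfing_generations: int = 7        # BIL: BC1F1 -> F8
    max_donor_segments: int = 3         # CSSL: retained under selection
    n_backcross: int = 4                # CSSL: backcrosses before fixation
    pool_factor: int = 30               # CSSL: candidate pool = factor x n_lines

    def __post_init__(self) -> None:
        if self.design not in ("CSSL", "BIL", "F2"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")


@dataclass(frozen=True)
class QTLEffect:
    """A planted QTL acting on a latent germination-curve parameter.

    ``param`` is one of ``gmax``, ``t50``, ``slope``. Dosage coding:
    recurrent hom contributes 0, het a+d, donor hom 2a.
    """

    param: str
    chrom: str
    pos: int
    additive: float
    dominance: float = 0.0

    def __post_init__(self) -> None:
        if self.param not in ("gmax", "t50", "slope"):
            raise ValueError(
                f"QTL effects act on latent curve parameters gmax/t50/slope, got {self.param!r}"
            )
        if not (np.isfinite(self.additive) and np.isfinite(self.dominance)):
            raise ValueError("effect sizes must be finite")


@dataclass(frozen=True)
class EpistaticEffect:
    """Additive-by-additive interaction ``aa * (x1 - 1) * (x2 - 1)``."""

    param: str
    locus1: tuple[str, int]
    locus2: tuple[str, int]
    aa: float


@dataclass
class TruthSet:
    """Planted ground truth: per-line ancestry mosaics and QTL effects."""

    ancestry: dict[str, dict[str, Seg]]  # line -> chrom -> (ends, dosage labels)
    effects: list[QTLEffect] = field(default_factory=list)
    epistasis: list[EpistaticEffect] = field(default_factory=list)
    genetic_values: pd.DataFrame | None = None
    coverage: float | None = None  # CSSL: fraction of genome under >=1 donor segment

    def dosage_at(self, line_id: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        return _ancestry_at(self.ancestry[line_id][chrom], np.asarray(positions))

    def donor_segments(self, line_id: str) -> list[tuple[str, int, int]]:
        """Homozygous donor intervals as (chrom, start0, end) half-open."""
        out = []
        for chrom, (ends, labels) in self.ancestry[line_id].items():
            starts = np.concatenate(([0], ends[:-1]))
            for s, e, l in zip(starts, ends, labels):
                if l == 2:
                    out.append((chrom, int(s), int(e)))
        return out

    def to_bed(self, path) -> None:
        names = {0: "recurrent", 1: "het", 2: "donor"}
        with open(path, "w") as fh:
            fh.write("# dormqtl ancestry truth; 0-based half-open intervals\n")
            for lid, per_chrom in self.ancestry.items():
                for chrom, (ends, labels) in per_chrom.items():
                    start = 0
                    for e, l in zip(ends, labels):
                        fh.write(f"{chrom}\t{start}\t{int(e)}\t{lid}\t{names[int(l)]}\n")
                        start = int(e)

    def effects_to_json(self, path) -> None:
        payload = {
            "effects": [vars(e) | {} for e in self.effects],
            "epistasis": [
                {"param": e.param, "locus1": list(e.locus1), "locus2": list(e.locus2), "aa": e.aa}
                for e in self.epistasis
            ],
            "coverage": self.coverage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _snp_matrix_from_ancestry(ancestry: dict[str, dict[str, Seg]],
                              gmap: GeneticMap) -> SNPMatrix:
    markers = gmap.marker_frame()
    line_ids = list(ancestry)
    calls = np.empty((len(line_ids), len(markers)), dtype="<U1")
    col = 0
    for chrom in gmap.chrom_ids:
        pos = gmap.marker_positions[chrom]
        for i, lid in enumerate(line_ids):
            calls[i, col:col + len(pos)] = _CALL[_ancestry_at(ancestry[lid][chrom], pos)]
        col += len(pos)
    return SNPMatrix(line_ids, markers, calls)


# ---------------------------------------------------------------------------
# Population designs
# ---------------------------------------------------------------------------

def simulate_bil_population(spec: PopulationSpec, gmap: GeneticMap,
                            seed: int | None = None) -> tuple[SNPMatrix, TruthSet]:
    """BC1F1 advanced by single-seed descent to near-homozygosity."""
    if spec.design != "BIL":
        raise ValueError("spec.design must be 'BIL'")
    rng = substream(seed if seed is not None else spec.seed, "bil")
    donor = _const_hap(gmap, DONOR)
    rec = _const_hap(gmap, REC)
    f1 = (donor, rec)
    ancestry: dict[str, dict[str, Seg]] = {}
    width = max(3, len(str(spec.n_lines)))
    for i in range(spec.n_lines):
        ind = (simulate_gamete(f1, gmap, rng), rec)  # BC1F1
        for _ in range(spec.selfing_generations):    # single-seed descent
            ind = (simulate_gamete(ind, gmap, rng), simulate_gamete(ind, gmap, rng))
        ancestry[f"BIL{i + 1:0{width}d}"] = {
            c: _diploid_mosaic(ind[0][c], ind[1][c]) for c in gmap.chrom_ids
        }
    return _snp_matrix_from_ancestry(ancestry, gmap), TruthSet(ancestry)


def simulate_f2_population(spec: PopulationSpec, gmap: GeneticMap,
                           seed: int | None = None) -> tuple[SNPMatrix, TruthSet]:
    """One selfing of the donor x recurrent F1."""
    if spec.design != "F2":
        raise ValueError("spec.design must be 'F2'")
    rng = substream(seed if seed is not None else spec.seed, "f2")
    f1 = (_const_hap(gmap, DONOR), _const_hap(gmap, REC))
    ancestry: dict[str, dict[str, Seg]] = {}
    width = max(3, len(str(spec.n_lines)))
    for i in range(spec.n_lines):
        ind = (simulate_gamete(f1, gmap, rng), simulate_gamete(f1, gmap, rng))
        ancestry[f"F2_{i + 1:0{width}d}"] = {
            c: _diploid_mosaic(ind[0][c], ind[1][c]) for c in gmap.chrom_ids
        }
    return _snp_matrix_from_ancestry(ancestry, gmap), TruthSet(ancestry)


class CSSLPoolError(RuntimeError):
    """Raised when the candidate pool cannot supply the requested lines."""


def simulate_cssl_population(spec: PopulationSpec, gmap: GeneticMap,
                             seed: int | None = None) -> tuple[SNPMatrix, TruthSet]:
    """Generate-and-select CSSL panel.

    Candidate introgressed haplotypes are produced by ``n_backcross``
    backcrosses to the recurrent parent and fixed by doubling; candidates
    with 1..max_donor_segments donor segments enter the pool, from which
    lines are picked greedily to maximize genome coverage (ties and the
    post-saturation fill follow pool order, so selection is deterministic).
    """
    if spec.design != "CSSL":
        raise ValueError("spec.design must be 'CSSL'")
    rng = substream(seed if seed is not None else spec.seed, "cssl")
    donor = _const_hap(gmap, DONOR)
    rec = _const_hap(gmap, REC)

    pool: list[dict[str, Seg]] = []
    attempts = 0
    target = spec.pool_factor * spec.n_lines
    max_attempts = 20 * target
    while len(pool) < target and attempts < max_attempts:
        attempts += 1
        ind = (simulate_gamete((donor, rec), gmap, rng), rec)  # BC1
        for _ in range(spec.n_backcross - 1):
            ind = (simulate_gamete(ind, gmap, rng), rec)
        introg = ind[0]
        n_seg = sum(int(np.sum(labels == DONOR)) for _, labels in introg.values())
        if 1 <= n_seg <= spec.max_donor_segments:
            pool.append(introg)
    if len(pool) < spec.n_lines:
        raise CSSLPoolError(
            f"candidate pool exhausted: {len(pool)} usable candidates from "
            f"{attempts} attempts (need {spec.n_lines}); raise pool_factor, "
            f"max_donor_segments, or lower n_backcross"
        )

    # greedy maximum-coverage selection over donor intervals
    def donor_intervals(hap: dict[str, Seg]) -> list[tuple[str, int, int]]:
        out = []
        for chrom, (ends, labels) in hap.items():
            starts = np.concatenate(([0], ends[:-1]))
            for s, e, l in zip(starts, ends, labels):
                if l == DONOR:
                    out.append((chrom, int(s), int(e)))
        return out

    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in gmap.chrom_ids}

    def gain(intervals) -> int:
        """New bp an interval set would add to the current covered union."""
        g = 0
        for chrom, s, e in intervals:
            pieces = [(s, e)]
            for cs, ce in covered[chrom]:
                nxt = []
                for lo, hi in pieces:
                    if hi <= cs or lo >= ce:  # disjoint from this covered piece
                        nxt.append((lo, hi))
                    else:
                        if lo < cs:
                            nxt.append((lo, cs))
                        if ce < hi:
                            nxt.append((ce, hi))
                pieces = nxt
            g += sum(hi - lo for lo, hi in pieces)
        return g

    cand_ivals = [donor_intervals(h) for h in pool]
    # lazy greedy: gains only shrink as coverage grows, so a stale heap entry
    # whose recomputed gain still tops the heap is the true argmax
    import heapq

    heap = [(-sum(e - s for _, s, e in iv), k) for k, iv in enumerate(cand_ivals)]
    heapq.heapify(heap)
    chosen: list[int] = []
    while len(chosen) < spec.n_lines and heap:
        neg_g, k = heapq.heappop(heap)
        g = gain(cand_ivals[k])
        if heap and (-g, k) > heap[0]:  # stale gain no longer tops the heap
            heapq.heappush(heap, (-g, k))
            continue
        chosen.append(k)
        for chrom, s, e in cand_ivals[k]:
            covered[chrom].append((s, e))

    cov_bp = 0
    for chrom, ivals in covered.items():
        cur_s, cur_e = None, None
        for s, e in sorted(ivals):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                cov_bp += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            cov_bp += cur_e - cur_s
    coverage = cov_bp / gmap.total_bp

    ancestry: dict[str, dict[str, Seg]] = {}
    width = max(3, len(str(spec.n_lines)))
    for i, k in enumerate(chosen):
        introg = pool[k]
        ancestry[f"CSSL{i + 1:0{width}d}"] = {
            c: (introg[c][0].copy(), (introg[c][1] * 2).astype(np.int8))  # fixed homozygous
            for c in gmap.chrom_ids
        }
    truth = TruthSet(ancestry, coverage=coverage)
    log.info("simulate_cssl_population: coverage %.3f from %d candidates", coverage, len(pool))
    return _snp_matrix_from_ancestry(ancestry, gmap), truth


def simulate_population(spec: PopulationSpec, gmap: GeneticMap,
                        seed: int | None = None) -> tuple[SNPMatrix, TruthSet]:
    fn = {
        "BIL": simulate_bil_population,
        "CSSL": simulate_cssl_population,
        "F2": simulate_f2_population,
    }[spec.design]
    return fn(spec, gmap, seed)


def add_missing_calls(m: SNPMatrix, rate: float, rng: np.random.Generator) -> SNPMatrix:
    """Return a copy with a fraction ``rate`` of cells set to missing."""
    calls = m.calls.copy()
    mask = rng.random(calls.shape) < rate
    calls[mask] = "-"
    return SNPMatrix(list(m.line_ids), m.markers, calls)


# ---------------------------------------------------------------------------
# Germination phenotypes
# ---------------------------------------------------------------------------

DEFAULT_TIMEPOINTS = tuple(range(24, 169, 24))  # scored every 24 h for 7 days


@dataclass(frozen=True)
class BaseCurve:
    """Latent curve of the recurrent (non-dormant) background."""

    gmax: float = 0.92
    t50: float = 60.0   # hours
    slope: float = 12.0  # hours


def latent_parameters(truth: TruthSet, effects: list[QTLEffect],
                      epistasis: list[EpistaticEffect] | None = None,
                      base: BaseCurve = BaseCurve(),
                      gmax_env_sd: float = 0.07, t50_env_sd: float = 10.0,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-line latent (gmax, t50, slope) after QTL, epistasis and line noise.

    Also records the pure genetic values (before environmental noise).
    """
    epistasis = epistasis or []
    lines = list(truth.ancestry)
    vals = {"gmax": np.full(len(lines), base.gmax),
            "t50": np.full(len(lines), base.t50),
            "slope": np.full(len(lines), base.slope)}
    dosages: dict[tuple[str, int], np.ndarray] = {}

    def dose(chrom: str, pos: int) -> np.ndarray:
        key = (chrom, pos)
        if key not in dosages:
            dosages[key] = np.array(
                [truth.dosage_at(lid, chrom, np.array([pos]))[0] for lid in lines], dtype=float
            )
        return dosages[key]

    for eff in effects:
        x = dose(eff.chrom, eff.pos)
        contrib = np.where(x == 2, 2 * eff.additive,
                           np.where(x == 1, eff.additive + eff.dominance, 0.0))
        vals[eff.param] = vals[eff.param] + contrib
    for ep in epistasis:
        x1 = dose(*ep.locus1)
        x2 = dose(*ep.locus2)
        vals[ep.param] = vals[ep.param] + ep.aa * (x1 - 1.0) * (x2 - 1.0)

    genetic = pd.DataFrame({"line_id": lines,
                            "gmax_genetic": vals["gmax"].copy(),
                            "t50_genetic": vals["t50"].copy()})
    if rng is not None:
        vals["gmax"] = vals["gmax"] + rng.normal(0.0, gmax_env_sd, len(lines))
        vals["t50"] = vals["t50"] + rng.normal(0.0, t50_env_sd, len(lines))

    n_clip = int(np.sum((vals["gmax"] < 0) | (vals["gmax"] > 1)))
    if n_clip:
        log.warning("latent gmax clipped to [0,1] for %d lines", n_clip)
    vals["gmax"] = np.clip(vals["gmax"], 0.0, 1.0)

    out = genetic.assign(gmax=vals["gmax"], t50=vals["t50"], slope=vals["slope"])
    return out


def simulate_germination(truth: TruthSet, effects: list[QTLEffect],
                         base_curve: BaseCurve = BaseCurve(),
                         epistasis: list[EpistaticEffect] | None = None,
                         n_seeds: int = 50,
                         timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS,
                         replicates: int = 3,
                         gmax_env_sd: float = 0.07, t50_env_sd: float = 10.0,
                         seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dish-level cumulative germination counts for every line.

    Returns (tidy counts frame, per-line latent parameter frame). Replicates
    are independent dishes of ``n_seeds`` seeds sharing the line's latent
    curve; counts are cumulative at each timepoint and non-decreasing by
    construction.
    """
    for eff in effects:
        if eff.chrom not in truth.ancestry[next(iter(truth.ancestry))]:
            raise ValueError(f"effect position {eff.chrom}:{eff.pos} not on the simulated map")
    rng = substream(seed, "germination")
    latents = latent_parameters(truth, effects, epistasis, base_curve,
                                gmax_env_sd, t50_env_sd, rng=rng)
    truth.effects = list(effects)
    truth.epistasis = list(epistasis or [])
    truth.genetic_values = latents[["line_id", "gmax_genetic", "t50_genetic"]].copy()

    tp = np.asarray(timepoints, dtype=float)
    records = []
    for row in latents.itertuples(index=False):
        for rep in range(1, replicates + 1):
            germinates = rng.random(n_seeds) < row.gmax
            if row.slope > 0:
                times = rng.logistic(row.t50, row.slope, n_seeds)
            else:
                times = np.full(n_seeds, row.t50)
            times = np.where(germinates, times, np.inf)
            counts = (times[None, :] <= tp[:, None]).sum(axis=1)
            for t, c in zip(timepoints, counts):
                records.append((row.line_id, rep, int(t), int(c), n_seeds))
    counts_df = pd.DataFrame(
        records, columns=["line_id", "replicate", "hour", "cumulative_count", "n_seeds"]
    )
    return counts_df, latents


# ---------------------------------------------------------------------------
# Study-condition defaults for the bundled fixtures
# ---------------------------------------------------------------------------

def default_study_effects(gmap: GeneticMap) -> list[QTLEffect]:
    """Four planted dormancy QTLs: three delaying germination via t50, one
    reducing maximum germination — donor (dormant-parent) alleles increase
    dormancy, each contributing roughly 10-20% of its primary trait's
    variance under the default noise model."""
    mids = {c: int(gmap.lengths_bp[c] // 2) for c in gmap.chrom_ids}
    chroms = list(gmap.chrom_ids)
    if len(chroms) < 4:
        raise ValueError("default effects need >= 4 chromosomes")
    return [
        QTLEffect("t50", chroms[0], mids[chroms[0]], additive=6.5),
        QTLEffect("t50", chroms[1], mids[chroms[1]], additive=6.5),
        QTLEffect("t50", chroms[2], mids[chroms[2]], additive=6.5),
        QTLEffect("gmax", chroms[3], mids[chroms[3]], additive=-0.04),
    ]
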