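"""Recovery metrics against simulator ground truth.

These helpers compare pipeline output (bin genotypes, declared QTLs) with a
:class:`~dormqtl.sim.TruthSet`; they exist for validation studies and the
package's own acceptance checks, not for real-data analysis.
"""

from __future__ import annotations

import numpy as np

from .binmap import BinGenotypes, BinMap
from .io import SNPMatrix
from .qtl import QTLRecord
from .sim import QTLEffect, TruthSet


def ancestry_concordance(bg: BinGenotypes, truth: TruthSet, snp: SNPMatrix,
                         min_run_markers: int = 30) -> tuple[int, int]:
    """Agreement between bin calls and true ancestry in long homozygous runs.

    A (line, bin) pair is eligible when every marker inside the bin lies in
    a truth run of a single homozygous ancestry (all donor-hom or all
    recurrent-hom) spanning at least ``min_run_markers`` markers — the
    window caller cannot be expected to resolve segments shorter than its
    own span. Returns (matching pairs, eligible pairs).
    """
    markers = snp.markers
    n_match = n_elig = 0
    for chrom in dict.fromkeys(bg.bins["chrom"]):
        msel = (markers["chrom"] == chrom).to_numpy()
        pos = markers.loc[msel, "pos"].to_numpy()
        bsel = (bg.bins["chrom"] == chrom).to_numpy()
        starts = bg.bins.loc[bsel, "start"].to_numpy()
        ends = bg.bins.loc[bsel, "end"].to_numpy()
        bcols = np.flatnonzero(bsel)
        for i, lid in enumerate(bg.line_ids):
            dos = truth.dosage_at(lid, chrom, pos)
            # run id and length per marker
            change = np.concatenate(([True], dos[1:] != dos[:-1]))
            run_id = np.cumsum(change) - 1
            run_len = np.bincount(run_id)
            ok = (run_len[run_id] >= min_run_markers) & ((dos == 0) | (dos == 2))
            # marker at 1-based pos p occupies [p-1, p): inside bin iff start < p <= end
            lo = np.searchsorted(pos, starts, side="right")
            hi = np.searchsorted(pos, ends, side="right")
            for k in range(len(starts)):
                sl = slice(lo[k], hi[k])
                if sl.start == sl.stop or not ok[sl].all():
                    continue
                d = dos[sl]
                if d.min() != d.max():
                    continue
                n_elig += 1
                expected = "A" if d[0] == 2 else "B"
                if bg.calls[i, bcols[k]] == expected:
                    n_match += 1
    return n_match, n_elig


def true_bin_index(bin_map: BinMap, chrom: str, pos: int) -> int:
    """Genome-order index of the bin containing 1-based position ``pos``."""
    bins = bin_map.bins
    sel = ((bins["chrom"] == chrom) & (bins["start"] < pos)
           & (bins["end"] >= pos)).to_numpy()
    idx = np.flatnonzero(sel)
    if idx.size != 1:
        raise ValueError(f"position {chrom}:{pos} not in exactly one bin")
    return int(idx[0])


def recovery_distances(records: list[QTLRecord], bin_map: BinMap,
                       effects: list[QTLEffect]) -> list[int]:
    """For each planted QTL, the bin distance to the closest declared peak
    on its chromosome (a large sentinel when no QTL was declared there)."""
    out = []
    for eff in effects:
        tb = true_bin_index(bin_map, eff.chrom, eff.pos)
        ds = [abs(r.peak_bin_index - tb) for r in records if r.chrom == eff.chrom]
        out.append(min(ds) if ds else 10 ** 6)
    return out
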