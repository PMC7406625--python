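"""Genotype matrix container and file formats.

The canonical in-memory object is :class:`SNPMatrix`: lines x ordered markers
of parental-origin calls. Calls use the four-letter alphabet

* ``A`` — homozygous for the donor allele (Nipponbare in the motivating cross)
* ``B`` — homozygous for the recurrent allele (9311)
* ``H`` — heterozygous
* ``-`` — missing (the only missing representation)

Marker coordinates are 1-based inclusive bp (VCF convention). All interval
output written by this package (BED) is 0-based half-open; every writer says
so in its header.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("dormqtl")

VALID_CALLS = frozenset("ABH-")


@dataclass
class SNPMatrix:
    """Lines x ordered markers of parental-origin genotype calls."""

    line_ids: list[str]
    markers: pd.DataFrame  # columns: chrom, pos, marker_id; genome-ordered
    calls: np.ndarray  # (n_lines, n_markers) of single characters

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.markers)} markers"
            )
        bad = set(np.unique(self.calls)) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}; expected A/B/H/-")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")

    # -- basic queries -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Column slice of the markers on one chromosome."""
        idx = np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def missing_fraction(self) -> pd.Series:
        frac = (self.calls == "-").mean(axis=1)
        return pd.Series(frac, index=self.line_ids, name="missing_fraction")

    def subset_lines(self, keep: list[str]) -> "SNPMatrix":
        index = {lid: i for i, lid in enumerate(self.line_ids)}
        rows = [index[lid] for lid in keep]
        return SNPMatrix(list(keep), self.markers, self.calls[rows].copy())


@dataclass
class QCReport:
    """Record of what quality control removed or rewrote."""

    per_line_missing: dict[str, float] = field(default_factory=dict)
    excluded_lines: list[str] = field(default_factory=list)
    het_recoded: int = 0
    dropped_markers: int = 0
    threshold: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "per_line_missing": self.per_line_missing,
                    "excluded_lines": self.excluded_lines,
                    "het_recoded": self.het_recoded,
                    "dropped_markers": self.dropped_markers,
                    "threshold": self.threshold,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


# ---------------------------------------------------------------------------
# CSV dialect
#
# row 1: line_id, <marker ids...>
# row 2: chrom,   <chrom per marker...>
# row 3: pos,     <1-based bp per marker...>
# rows 4+: one line per row, cells in {A,B,H,-}
# ---------------------------------------------------------------------------

def write_genotypes_csv(m: SNPMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["line_id", *m.markers["marker_id"]])
        w.writerow(["chrom", *m.markers["chrom"]])
        w.writerow(["pos", *(str(p) for p in m.markers["pos"])])
        for i, lid in enumerate(m.line_ids):
            w.writerow([lid, *m.calls[i]])


def read_genotypes_csv(path) -> SNPMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError(f"{path}: expected marker-id/chrom/pos headers plus >=1 line")
    header, chrom_row, pos_row = rows[0], rows[1], rows[2]
    if chrom_row[0] != "chrom" or pos_row[0] != "pos":
        raise ValueError(f"{path}: second/third header rows must start with 'chrom'/'pos'")
    marker_ids = header[1:]
    markers = pd.DataFrame(
        {"chrom": chrom_row[1:], "pos": [int(p) for p in pos_row[1:]], "marker_id": marker_ids}
    )
    line_ids, calls = [], []
    for r, row in enumerate(rows[3:], start=4):
        if not row:
            continue
        line_ids.append(row[0])
        cells = row[1:]
        if len(cells) != len(marker_ids):
            raise ValueError(f"{path}:{r}: expected {len(marker_ids)} calls, got {len(cells)}")
        for c, cell in enumerate(cells):
            if cell not in VALID_CALLS:
                raise ValueError(
                    f"{path}:{r}: unknown genotype code {cell!r} for line {row[0]} "
                    f"marker {marker_ids[c]}"
                )
        calls.append(cells)
    return SNPMatrix(line_ids, markers, np.array(calls, dtype="<U1"))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT = {"A": "1/1", "B": "0/0", "H": "0/1", "-": "./."}


def write_genotypes_vcf(m: SNPMatrix, path, donor_sample: str = "NIP",
                        recurrent_sample: str = "9311",
                        chrom_lengths: dict[str, int] | None = None) -> None:
    """Write calls as VCF v4.2 with the two parents as leading samples.

    REF is the recurrent allele, ALT the donor allele, so donor homozygotes
    are 1/1 and recurrent homozygotes 0/0. The parent columns make the file
    self-polarizing for :func:`read_genotypes`.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dormqtl\n")
        if chrom_lengths:
            for chrom, ln in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        else:
            for chrom in m.chroms:
                last = int(m.markers.loc[m.markers["chrom"] == chrom, "pos"].max())
                fh.write(f"##contig=<ID={chrom},length={last + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                donor_sample, recurrent_sample, *m.line_ids]
        fh.write("\t".join(cols) + "\n")
        for j in range(m.n_markers):
            chrom = m.markers["chrom"].iat[j]
            pos = m.markers["pos"].iat[j]
            mid = m.markers["marker_id"].iat[j]
            gts = ["1/1", "0/0"] + [_GT[m.calls[i, j]] for i in range(m.n_lines)]
            fh.write(f"{chrom}\t{pos}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_genotypes_vcf(path, donor_sample: str, recurrent_sample: str) -> SNPMatrix:
    """Read a VCF and polarize calls by the two parental samples.

    Markers where either parent is heterozygous or missing, or where both
    parents carry the same allele, are uninformative for parental origin and
    dropped (count logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in (donor_sample, recurrent_sample):
        if s not in samples:
            raise ValueError(f"parental sample {s!r} not in VCF samples {samples}")
    di = samples.index(donor_sample)
    ri = samples.index(recurrent_sample)
    line_idx = [k for k, s in enumerate(samples) if s not in (donor_sample, recurrent_sample)]
    line_ids = [samples[k] for k in line_idx]

    chroms, positions, ids, columns = [], [], [], []
    dropped = 0
    last_pos: dict[str, int] = {}
    for v in vcf:
        g = v.genotypes  # [[a0, a1, phased], ...]
        dg, rg = g[di], g[ri]
        if dg[0] < 0 or rg[0] < 0 or dg[0] != dg[1] or rg[0] != rg[1] or dg[0] == rg[0]:
            dropped += 1
            continue
        if v.CHROM in last_pos and v.POS <= last_pos[v.CHROM]:
            raise ValueError(f"{path}: unsorted positions on {v.CHROM} at {v.POS}")
        last_pos[v.CHROM] = v.POS
        donor_allele, rec_allele = dg[0], rg[0]
        col = []
        for k in line_idx:
            a0, a1 = g[k][0], g[k][1]
            if a0 < 0 or a1 < 0:
                col.append("-")
            elif a0 == a1 == donor_allele:
                col.append("A")
            elif a0 == a1 == rec_allele:
                col.append("B")
            elif {a0, a1} == {donor_allele, rec_allele}:
                col.append("H")
            else:
                col.append("-")
        chroms.append(v.CHROM)
        positions.append(v.POS)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        columns.append(col)
    if dropped:
        log.info("read_genotypes_vcf: dropped %d unpolarizable markers", dropped)
    markers = pd.DataFrame({"chrom": chroms, "pos": positions, "marker_id": ids})
    calls = np.array(columns, dtype="<U1").T if columns else np.empty((len(line_ids), 0), "<U1")
    return SNPMatrix(line_ids, markers, calls)


def read_genotypes(path, format: str, donor_sample: str = "NIP",
                   recurrent_sample: str = "9311") -> SNPMatrix:
    """Read a genotype matrix from ``vcf`` or the package ``csv`` dialect."""
    if format == "vcf":
        return read_genotypes_vcf(path, donor_sample, recurrent_sample)
    if format == "csv":
        return read_genotypes_csv(path)
    raise ValueError(f"unknown genotype format {format!r}; expected 'vcf' or 'csv'")


# ---------------------------------------------------------------------------
# Germination counts: tidy CSV (line, replicate, hour, cumulative_count, n_seeds)
# ---------------------------------------------------------------------------

def write_counts_csv(df: pd.DataFrame, path) -> None:
    cols = ["line_id", "replicate", "hour", "cumulative_count", "n_seeds"]
    df[cols].to_csv(path, index=False)


def read_counts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"line_id", "replicate", "hour", "cumulative_count", "n_seeds"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
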