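"""Genotype quality control for substitution-line populations.

Two rules are applied before bin calling, both taken from the motivating
study's handling of its backcross inbred lines:

* heterozygous calls are treated as missing — BILs are near-fixed after
  seven selfing generations, so a residual ``H`` carries no reliable
  parental-origin signal for a whole window;
* lines with strictly more than 20% missing calls are excluded.

The het recoding is applied to BILs by default; CSSL het calls are kept as
``H`` (the window caller already ignores them as non-informative).
"""

from __future__ import annotations

import logging

from .io import QCReport, SNPMatrix

log = logging.getLogger("dormqtl")


def recode_het_to_missing(m: SNPMatrix) -> tuple[SNPMatrix, int]:
    """Replace every ``H`` with ``-``; returns (matrix, number recoded)."""
    calls = m.calls.copy()
    het = calls == "H"
    n = int(het.sum())
    calls[het] = "-"
    return SNPMatrix(list(m.line_ids), m.markers, calls), n


def filter_lines_by_missingness(m: SNPMatrix, threshold: float = 0.20
                                ) -> tuple[SNPMatrix, QCReport]:
    """Drop lines whose missing fraction is strictly greater than ``threshold``.

    Boundary lines (missing fraction exactly equal to the threshold) are
    kept. Markers are never reordered or removed. Raises if nothing is left.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    frac = m.missing_fraction()
    keep = [lid for lid in m.line_ids if frac[lid] <= threshold]
    excluded = [lid for lid in m.line_ids if frac[lid] > threshold]
    if not keep:
        raise ValueError(
            f"all {m.n_lines} lines exceed the {threshold:.0%} missingness threshold"
        )
    report = QCReport(
        per_line_missing={lid: float(frac[lid]) for lid in m.line_ids},
        excluded_lines=excluded,
        threshold=threshold,
    )
    if excluded:
        log.info("filter_lines_by_missingness: excluded %d of %d lines (> %.0f%% missing)",
                 len(excluded), m.n_lines, 100 * threshold)
    return m.subset_lines(keep), report


def qc_pipeline(m: SNPMatrix, design: str = "BIL", threshold: float = 0.20,
                recode_het: bool | None = None) -> tuple[SNPMatrix, QCReport]:
    """Standard QC: optional het->missing recode, then line-missingness filter.

    ``recode_het`` defaults to True for BILs and False otherwise; pass a
    bool to override.
    """
    if recode_het is None:
        recode_het = design.upper() == "BIL"
    n_recoded = 0
    if recode_het:
        m, n_recoded = recode_het_to_missing(m)
    m, report = filter_lines_by_missingness(m, threshold)
    report.het_recoded = n_recoded
    return m, report
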