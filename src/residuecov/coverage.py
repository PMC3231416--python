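"""Percent residue cover per image and aggregated over an image set.

Coverage is the fraction of pixels labeled residue, expressed in
percent. Aggregating over a set uses the pixel-weighted mean, which
equals pooling every pixel of every image into one count (and reduces
to the simple mean when all images share dimensions). Because the
aggregate is a convex combination of per-image values, signed
per-image errors against the templates partially cancel in the
aggregate — the set-level estimate is typically far more accurate than
any single image's.

Similarity between a computed mask and its template is reported as
100 * (1 - S), with S the mean absolute pixel difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ga_tuning import fitness

__all__ = ["CoverageReport", "coverage_fraction", "similarity_pct", "quantify_set"]

PER_IMAGE_COLUMNS = [
    "identifier",
    "coverage_pct",
    "template_coverage_pct",
    "similarity_pct",
    "coverage_error_pct",
]


@dataclass
class CoverageReport:
    """Per-image rows plus pixel-weighted aggregate coverage."""

    per_image: pd.DataFrame  # columns PER_IMAGE_COLUMNS
    aggregate_computed_pct: float
    aggregate_template_pct: Optional[float] = None

    @property
    def aggregate_error_pct(self) -> Optional[float]:
        if self.aggregate_template_pct is None:
            return None
        return self.aggregate_computed_pct - self.aggregate_template_pct

    def to_frame(self) -> pd.DataFrame:
        """Per-image rows plus a final 'aggregate' row, percents to 2 decimals."""
        frame = self.per_image.copy()
        frame.loc[len(frame)] = {
            "identifier": "aggregate",
            "coverage_pct": self.aggregate_computed_pct,
            "template_coverage_pct": self.aggregate_template_pct,
            "similarity_pct": None,
            "coverage_error_pct": self.aggregate_error_pct,
        }
        for col in PER_IMAGE_COLUMNS[1:]:
            frame[col] = frame[col].astype(float).round(2)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        out = {
            "n_images": int(len(self.per_image)),
            "aggregate_computed_pct": round(self.aggregate_computed_pct, 2),
        }
        if self.aggregate_template_pct is not None:
            out["aggregate_template_pct"] = round(self.aggregate_template_pct, 2)
            out["aggregate_error_pct"] = round(self.aggregate_error_pct, 2)
        return out


def coverage_fraction(mask: np.ndarray) -> float:
    """Percent of pixels labeled 1: 100 * count / (n * m)."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("mask is empty")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def similarity_pct(computed: np.ndarray, template: np.ndarray) -> float:
    """100 * (1 - S): 100 for identical masks, 0 for complements."""
    return 100.0 * (1.0 - fitness(computed, template))


def quantify_set(
    pairs: Sequence[tuple[np.ndarray, Optional[np.ndarray]]],
    identifiers: Optional[Sequence[str]] = None,
) -> CoverageReport:
    """Build a CoverageReport from (computed mask, template-or-None) pairs.

    Aggregate coverage is the pooled-pixel count: sum of residue pixels
    over the set divided by the total pixel count. The aggregate
    template coverage is reported only when every pair has a template.
    """
    if len(pairs) == 0:
        raise ValueError("no masks to quantify")
    if identifiers is None:
        identifiers = [f"image_{i:03d}" for i in range(len(pairs))]
    if len(identifiers) != len(pairs):
        raise ValueError("identifiers and pairs differ in length")

    rows = []
    computed_ones = computed_px = 0
    template_ones = template_px = 0
    all_templates = True
    for ident, (computed, template) in zip(identifiers, pairs):
        computed = np.asarray(computed)
        cov = coverage_fraction(computed)
        computed_ones += int(np.count_nonzero(computed))
        computed_px += computed.size
        row = {
            "identifier": ident,
            "coverage_pct": cov,
            "template_coverage_pct": None,
            "similarity_pct": None,
            "coverage_error_pct": None,
        }
        if template is not None:
            template = np.asarray(template)
            tcov = coverage_fraction(template)
            row["template_coverage_pct"] = tcov
            row["similarity_pct"] = similarity_pct(computed, template)
            row["coverage_error_pct"] = cov - tcov
            template_ones += int(np.count_nonzero(template))
            template_px += template.size
        else:
            all_templates = False
        rows.append(row)

    aggregate_computed = 100.0 * computed_ones / computed_px
    aggregate_template = (
        100.0 * template_ones / template_px if all_templates else None
    )
    return CoverageReport(
        per_image=pd.DataFrame(rows, columns=PER_IMAGE_COLUMNS),
        aggregate_computed_pct=aggregate_computed,
        aggregate_template_pct=aggregate_template,
    )
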