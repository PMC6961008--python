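"""Overlap-based matching of delineated crowns against reference crowns.

Each reference crown is scored by its best-overlapping segment:
overlap = 100 * |segment ∩ reference| / |reference|.  Overlap above 50 %
makes the reference *matched*, between 25 % and 50 % (inclusive at both
category floors) *partially matched*, and below 25 % *omitted*.  The same
categories computed with segment areas as denominators give the user's-side
view.  Producer's accuracy is the matched (or matched + partial) fraction of
references; user's accuracy the analogue over segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchReport",
    "crown_overlap",
    "categorize_matches",
    "accuracy_summary",
    "summary_from_counts",
]

MATCHED_THRESH = 50.0
PARTIAL_THRESH = 25.0


@dataclass
class MatchReport:
    """Per-crown categories, counts, and the four accuracy summaries."""

    reference_categories: dict[int, str] = field(default_factory=dict)
    reference_best_overlap: dict[int, float] = field(default_factory=dict)
    segment_categories: dict[int, str] = field(default_factory=dict)
    segment_best_overlap: dict[int, float] = field(default_factory=dict)

    # boundary convention: overlap == 50 or == 25 falls in the lower category
    # (partially matched); recorded here so serialized reports are explicit.
    boundary_rule: str = "closed-on-lower-category"

    @staticmethod
    def _count(categories: dict[int, str]) -> tuple[int, int, int]:
        vals = list(categories.values())
        return (
            vals.count("matched"),
            vals.count("partially_matched"),
            vals.count("omitted"),
        )

    @property
    def counts(self) -> dict[str, int]:
        rm, rp, ro = self._count(self.reference_categories)
        sm, sp, so = self._count(self.segment_categories)
        return {
            "reference_matched": rm,
            "reference_partial": rp,
            "reference_omitted": ro,
            "segment_matched": sm,
            "segment_partial": sp,
            "segment_omitted": so,
        }

    @property
    def n_references(self) -> int:
        return len(self.reference_categories)

    @property
    def n_segments(self) -> int:
        return len(self.segment_categories)

    def to_dict(self) -> dict:
        out = dict(self.counts)
        out.update(accuracy_summary(self))
        out["n_references"] = self.n_references
        out["n_segments"] = self.n_segments
        out["boundary_rule"] = self.boundary_rule
        return out


def crown_overlap(segment_pixels: np.ndarray, reference_pixels: np.ndarray) -> float:
    """Percentage of the reference covered by the segment.

    Both arguments are boolean pixel masks on the same grid.
    """
    seg = np.asarray(segment_pixels, dtype=bool)
    ref = np.asarray(reference_pixels, dtype=bool)
    if seg.shape != ref.shape:
        raise ValueError("segment and reference grids differ in shape")
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValueError("reference crown has no pixels")
    return 100.0 * float((seg & ref).sum()) / n_ref


def _categorize(best: float) -> str:
    if best > MATCHED_THRESH:
        return "matched"
    if best >= PARTIAL_THRESH:
        return "partially_matched"
    return "omitted"


def categorize_matches(label_map: np.ndarray, reference_map: np.ndarray) -> MatchReport:
    """Score every reference crown and every segment by best overlap.

    ``label_map`` and ``reference_map`` are integer rasters (0 = background).
    Each reference independently takes its best-overlapping segment — one
    segment may be the best match of several references, which is how
    commission errors surface.
    """
    seg = np.asarray(label_map).astype(np.int64)
    ref = np.asarray(reference_map).astype(np.int64)
    if seg.shape != ref.shape:
        raise ValueError("label map and reference map differ in shape")

    seg_ids = np.unique(seg[seg > 0])
    ref_ids = np.unique(ref[ref > 0])
    report = MatchReport()
    if len(ref_ids) == 0:
        for s in seg_ids:
            report.segment_categories[int(s)] = "omitted"
            report.segment_best_overlap[int(s)] = 0.0
        return report

    # joint histogram of (segment id, reference id) pixel counts
    n_seg = int(seg.max()) + 1
    n_ref = int(ref.max()) + 1
    joint = np.zeros((n_seg, n_ref), dtype=np.int64)
    np.add.at(joint, (seg.ravel(), ref.ravel()), 1)
    seg_area = joint[:, :].sum(axis=1)
    ref_area = joint[:, :].sum(axis=0)
    inter = joint[1:, 1:]  # drop background row/col

    for j, rid in enumerate(ref_ids):
        col = inter[:, rid - 1]
        best = 100.0 * (col.max() / ref_area[rid]) if col.size else 0.0
        report.reference_best_overlap[int(rid)] = float(best)
        report.reference_categories[int(rid)] = _categorize(float(best))
    for sid in seg_ids:
        row = inter[sid - 1, :]
        area = seg_area[sid]
        best = 100.0 * (row.max() / area) if row.size and area else 0.0
        report.segment_best_overlap[int(sid)] = float(best)
        report.segment_categories[int(sid)] = _categorize(float(best))
    return report


def accuracy_summary(report: MatchReport) -> dict[str, float]:
    """Producer's and user's accuracies, with and without partial matches.

    Variant 1 counts matched crowns only; variant 2 counts matched plus
    partially matched.  Producer's side divides by the number of reference
    crowns, user's side by the number of segments.
    """
    n_ref = report.n_references
    if n_ref == 0:
        raise ValueError("accuracy_summary needs at least one reference crown")
    c = report.counts
    out = {
        "producer_acc_matched": c["reference_matched"] / n_ref,
        "producer_acc_matched_plus_partial": (c["reference_matched"] + c["reference_partial"])
        / n_ref,
    }
    n_seg = report.n_segments
    if n_seg:
        out["user_acc_matched"] = c["segment_matched"] / n_seg
        out["user_acc_matched_plus_partial"] = (c["segment_matched"] + c["segment_partial"]) / n_seg
    else:
        out["user_acc_matched"] = 0.0
        out["user_acc_matched_plus_partial"] = 0.0
    return out


def summary_from_counts(matched: int, partial: int, omitted: int) -> dict[str, float]:
    """Producer's accuracies straight from category counts."""
    total = matched + partial + omitted
    if total == 0:
        raise ValueError("no reference crowns")
    return {
        "producer_acc_matched": matched / total,
        "producer_acc_matched_plus_partial": (matched + partial) / total,
    }
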