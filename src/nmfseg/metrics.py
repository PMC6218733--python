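"""Dice and sensitivity over the three standard evaluation regions.

Regions are derived from the label map: complete tumor = labels
{1,2,3,4}, tumor core = {1,3,4}, enhancing tumor = {4}.  Metrics are
computed in 3D over whole volumes.  Empty-vs-empty masks score 1
(vacuous perfect match); empty-vs-nonempty scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeMismatchError
from .volume_io import BinaryMask, LabelMap

REGION_LABELS = {
    "complete": (1, 2, 3, 4),
    "core": (1, 3, 4),
    "enhancing": (4,),
}
REGION_TITLES = {
    "complete": "Complete tumor",
    "core": "Tumor core",
    "enhancing": "Enhancing tumor",
}


@dataclass
class RegionScore:
    dice: float
    sensitivity: float
    n_pred: int
    n_truth: int
    n_overlap: int


@dataclass
class EvalReport:
    """Per-region scores keyed 'complete' / 'core' / 'enhancing'."""

    regions: dict

    def as_dict(self) -> dict:
        return {
            name: {
                "dice": s.dice,
                "sensitivity": s.sensitivity,
                "n_pred": s.n_pred,
                "n_truth": s.n_truth,
                "n_overlap": s.n_overlap,
            }
            for name, s in self.regions.items()
        }


def region_mask(label_map: LabelMap, region: str) -> BinaryMask:
    """Binary mask of one evaluation region."""
    if region not in REGION_LABELS:
        raise KeyError(f"unknown region {region!r}; expected one of {sorted(REGION_LABELS)}")
    data = np.isin(label_map.data, REGION_LABELS[region])
    return BinaryMask(data=data)


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.data
    return np.asarray(mask, dtype=bool)


def dice(pred, truth) -> float:
    """2|A∩B| / (|A|+|B|); both-empty gives 1, one-empty gives 0."""
    a, b = _as_bool(pred), _as_bool(truth)
    if a.shape != b.shape:
        raise ShapeMismatchError("dice: shape mismatch")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def sensitivity(pred, truth) -> float:
    """|A∩B| / |B| with the truth as B; empty truth gives 1."""
    a, b = _as_bool(pred), _as_bool(truth)
    if a.shape != b.shape:
        raise ShapeMismatchError("sensitivity: shape mismatch")
    nb = int(b.sum())
    if nb == 0:
        return 1.0
    return int((a & b).sum()) / nb


def evaluate(pred: LabelMap, truth: LabelMap) -> EvalReport:
    """Dice + sensitivity for every evaluation region, with raw counts."""
    if pred.data.shape != truth.data.shape:
        raise ShapeMismatchError("evaluate: label map shapes differ")
    regions = {}
    for name in REGION_LABELS:
        a = region_mask(pred, name).data
        b = region_mask(truth, name).data
        regions[name] = RegionScore(
            dice=dice(a, b),
            sensitivity=sensitivity(a, b),
            n_pred=int(a.sum()),
            n_truth=int(b.sum()),
            n_overlap=int((a & b).sum()),
        )
    return EvalReport(regions=regions)


def format_report(report: EvalReport) -> str:
    """Small fixed-width table: region x (dice, sensitivity, counts)."""
    lines = [
        f"{'Class':<18}{'Dice':>8}{'Sensitivity':>14}{'|A|':>9}{'|B|':>9}{'|A∩B|':>9}"
    ]
    for name in REGION_LABELS:
        s = report.regions[name]
        lines.append(
            f"{REGION_TITLES[name]:<18}{s.dice:>8.4f}{s.sensitivity:>14.4f}"
            f"{s.n_pred:>9d}{s.n_truth:>9d}{s.n_overlap:>9d}"
        )
    return "\n".join(lines) + "\n"


def write_report(report: EvalReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(format_report(report))
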