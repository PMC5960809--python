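"""Scoring of lesion detections against ground truth.

Detected candidates are matched one-to-one to ground-truth lesions by
greedy ascending centroid distance with a distance gate (default 5 mm,
half the largest target lesion diameter).  Matched pairs are true
positives, unmatched truths false negatives, unmatched candidates false
positives.  Sensitivity is pooled over all lesions of a cohort
(TP / (TP + FN)), the same arithmetic as quoting "65 of 67 detected".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: Matching gate in mm: half of the 10 mm maximum target lesion diameter.
MATCH_DIST_DEFAULT = 5.0


@dataclass
class GroundTruthLesion:
    """A known lesion: physical centroid (mm), diameter (mm), free-text label."""

    centroid: np.ndarray
    diameter_mm: float
    label: str = ""
    hu: float = float("nan")

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=np.float64).reshape(3)
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be positive")

    @property
    def oversized(self) -> bool:
        """True for lesions above the 10 mm small-hemorrhage class."""
        return self.diameter_mm > 10.0


@dataclass
class SubjectScore:
    subject: str
    tp: int
    fp: int
    fn: int
    matches: list = field(default_factory=list)  # (cand_idx, truth_idx, dist_mm)


@dataclass
class CohortResult:
    """Pooled detection scores for a cohort of subjects."""

    subjects: list
    tp: int
    fp: int
    fn: int
    sensitivity: float | None

    def to_dict(self) -> dict:
        return {
            "n_subjects": len(self.subjects),
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "n_truth": self.tp + self.fn,
            "sensitivity": self.sensitivity,
            "per_subject": [
                {
                    "subject": s.subject,
                    "tp": s.tp,
                    "fp": s.fp,
                    "fn": s.fn,
                    "matches": [
                        {"candidate": int(c), "truth": int(t), "dist_mm": round(float(d), 4)}
                        for c, t, d in s.matches
                    ],
                }
                for s in self.subjects
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_table(self) -> str:
        lines = ["subject\tTP\tFP\tFN"]
        for s in self.subjects:
            lines.append(f"{s.subject}\t{s.tp}\t{s.fp}\t{s.fn}")
        sens = "n/a" if self.sensitivity is None else f"{self.sensitivity:.3f}"
        lines.append(f"pooled\t{self.tp}\t{self.fp}\t{self.fn}\tsensitivity={sens}")
        return "\n".join(lines)


def match(candidates, truths, max_dist: float = MATCH_DIST_DEFAULT, subject: str = "") -> SubjectScore:
    """Greedy one-to-one matching by ascending centroid distance.

    ``candidates`` may be detector LesionCandidate objects or anything with
    a ``centroid`` attribute / (3,) array; likewise ``truths``.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")

    def _centroid(obj) -> np.ndarray:
        c = getattr(obj, "centroid", obj)
        return np.asarray(c, dtype=np.float64).reshape(3)

    cand_pts = np.array([_centroid(c) for c in candidates]).reshape(-1, 3)
    truth_pts = np.array([_centroid(t) for t in truths]).reshape(-1, 3)
    pairs = []
    for i in range(len(cand_pts)):
        d = np.linalg.norm(truth_pts - cand_pts[i], axis=1) if len(truth_pts) else np.array([])
        for j in np.nonzero(d <= max_dist)[0]:
            pairs.append((float(d[j]), i, int(j)))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for d, i, j in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        matches.append((i, j, d))
    tp = len(matches)
    return SubjectScore(
        subject=subject,
        tp=tp,
        fp=len(cand_pts) - tp,
        fn=len(truth_pts) - tp,
        matches=matches,
    )


def evaluate_cohort(subjects, max_dist: float = MATCH_DIST_DEFAULT) -> CohortResult:
    """Pool per-subject matching into cohort sensitivity and FP totals.

    ``subjects`` is an iterable of ``(candidates, truths)`` pairs or
    ``(name, candidates, truths)`` triples.
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("need at least one subject")
    scores = []
    for k, item in enumerate(subjects):
        if len(item) == 3:
            name, cands, truths = item
        else:
            cands, truths = item
            name = f"subject_{k:02d}"
        scores.append(match(cands, truths, max_dist=max_dist, subject=str(name)))
    tp = sum(s.tp for s in scores)
    fp = sum(s.fp for s in scores)
    fn = sum(s.fn for s in scores)
    sens = None if tp + fn == 0 else round(tp / (tp + fn), 3)
    return CohortResult(subjects=scores, tp=tp, fp=fp, fn=fn, sensitivity=sens)


def threshold_sweep(detect_fn, thresholds, truths, max_dist: float = MATCH_DIST_DEFAULT):
    """Unscored helper: sensitivity/FP as a function of a detection threshold.

    ``detect_fn(thr)`` must return the candidate list at threshold ``thr``.
    """
    rows = []
    for thr in thresholds:
        s = match(detect_fn(thr), truths, max_dist=max_dist)
        denom = s.tp + s.fn
        rows.append({
            "threshold": float(thr),
            "tp": s.tp,
            "fp": s.fp,
            "fn": s.fn,
            "sensitivity": None if denom == 0 else s.tp / denom,
        })
    return rows


# ---------------------------------------------------------------------------
# Ground-truth / candidate TSV plumbing (schema shared with the phantom
# generator and the detector CLI)
# ---------------------------------------------------------------------------

TRUTH_HEADER = "subject\tz_mm\ty_mm\tx_mm\tdiameter_mm\tlabel"


def write_truth_tsv(path, rows) -> None:
    """Write ground truth as TSV; rows are (subject, GroundTruthLesion)."""
    lines = [TRUTH_HEADER]
    for subject, les in rows:
        z, y, x = les.centroid
        lines.append(
            f"{subject}\t{z:.6f}\t{y:.6f}\t{x:.6f}\t{les.diameter_mm:.6f}\t{les.label}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_tsv(path) -> dict[str, list[GroundTruthLesion]]:
    """Read a ground-truth TSV into {subject: [lesions]}."""
    out: dict[str, list[GroundTruthLesion]] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split("\t")[:5] != TRUTH_HEADER.split("\t")[:5]:
            raise ValueError(f"unexpected truth header: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            subj, z, y, x, d, *label = line.split("\t")
            out.setdefault(subj, []).append(
                GroundTruthLesion(
                    centroid=np.array([float(z), float(y), float(x)]),
                    diameter_mm=float(d),
                    label=label[0] if label else "",
                )
            )
    return out
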