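"""Patient-level, stratified, seeded train/validation/test splitting.

Whole patients (with all their scans) are assigned to exactly one split
so that no image from a held-out patient can leak into training.
Stratification is by (diagnosis, age group, sex); within each stratum
patients are shuffled under the seed and apportioned 70/20/10 (or any
configured ratios) by the largest-remainder rule on patient counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientRecord, largest_remainder

SPLITS = ("train", "validation", "test")
DEFAULT_RATIOS = (0.7, 0.2, 0.1)
MIN_STRATUM = 3


@dataclass
class CohortSplit:
    train: set[str]
    validation: set[str]
    test: set[str]
    ratios: tuple[float, float, float]
    seed: int
    stratum_table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [self.train, self.validation, self.test]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("split patient sets must be pairwise disjoint")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")

    def split_of(self, patient_id: str) -> str:
        for name in SPLITS:
            if patient_id in getattr(self, name):
                return name
        raise KeyError(patient_id)

    @property
    def all_patients(self) -> set[str]:
        return self.train | self.validation | self.test


def _strata(patients: list[PatientRecord]) -> dict[tuple, list[PatientRecord]]:
    strata: dict[tuple, list[PatientRecord]] = {}
    for p in patients:
        strata.setdefault((p.diagnosis, p.age_group, p.sex), []).append(p)
    # merge strata below the minimum into a pooled per-diagnosis stratum so
    # apportionment does not degenerate on singleton cells
    merged: dict[tuple, list[PatientRecord]] = {}
    for key, members in sorted(strata.items()):
        if len(members) < MIN_STRATUM:
            merged.setdefault((key[0], "pooled", "pooled"), []).extend(members)
        else:
            merged[key] = members
    return merged


def assign_splits(
    patients: list[PatientRecord],
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = 42,
) -> CohortSplit:
    """Stratified largest-remainder assignment of patients to splits.

    Patients are sorted lexicographically by id before the seeded
    shuffle, so the split is invariant to input order; a fixed seed gives
    an identical split.
    """
    if not patients:
        raise ValueError("no patients to split")
    r = np.asarray(ratios, float)
    if len(r) != 3 or abs(r.sum() - 1.0) > 1e-9 or np.any(r < 0):
        raise ValueError(f"ratios must be 3 nonnegative values summing to 1, got {ratios}")
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")

    rng = np.random.default_rng(seed)
    assignment: dict[str, list[str]] = {s: [] for s in SPLITS}
    stratum_table: dict = {}
    for key, members in sorted(_strata(patients).items()):
        members = sorted(members, key=lambda p: p.patient_id)
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        counts = largest_remainder(len(members), r)
        pos = 0
        row = {}
        for split_name, c in zip(SPLITS, counts):
            assignment[split_name].extend(p.patient_id for p in shuffled[pos:pos + c])
            row[split_name] = int(c)
            pos += c
        stratum_table[key] = row

    return CohortSplit(
        train=set(assignment["train"]),
        validation=set(assignment["validation"]),
        test=set(assignment["test"]),
        ratios=tuple(float(x) for x in r),
        seed=seed,
        stratum_table=stratum_table,
    )


@dataclass
class LeakageReport:
    passed: bool
    offending_patients: list[str]


def verify_no_leakage(
    split: CohortSplit,
    scan_table: dict[str, str],
    scan_assignment: dict[str, str] | None = None,
) -> LeakageReport:
    """Machine check that no patient's scans appear in two splits.

    ``scan_table`` maps scan_id -> patient_id; every scan must map to a
    patient known to the split (orphans raise). The patient-set
    disjointness check runs first. If ``scan_assignment`` (scan_id ->
    split name, e.g. from a downstream dataset manifest) is given, each
    patient's scans must all sit in that patient's split.
    """
    offenders = sorted(split.train & split.validation | split.train & split.test
                       | split.validation & split.test)
    if offenders:
        return LeakageReport(passed=False, offending_patients=offenders)
    known = split.all_patients
    seen: dict[str, set[str]] = {}
    for scan_id, pid in scan_table.items():
        if pid not in known:
            raise ValueError(f"orphan scan {scan_id!r}: unknown patient {pid!r}")
        seen.setdefault(pid, set()).add(split.split_of(pid))
        if scan_assignment is not None and scan_id in scan_assignment:
            seen[pid].add(scan_assignment[scan_id])
    bad = sorted(pid for pid, splits in seen.items() if len(splits) > 1)
    return LeakageReport(passed=not bad, offending_patients=bad)


def split_summary(split: CohortSplit, patients: list[PatientRecord]) -> pd.DataFrame:
    """Per-split patient/image counts and class percentages."""
    by_id = {p.patient_id: p for p in patients}
    rows = []
    for name in SPLITS:
        members = [by_id[pid] for pid in sorted(getattr(split, name))]
        n_pat = len(members)
        n_img = sum(len(p.scan_ids) for p in members)
        row = {"split": name, "n_patients": n_pat, "n_images": n_img}
        for cls in ("CN", "MCI", "AD"):
            n_cls = sum(len(p.scan_ids) for p in members if p.diagnosis == cls)
            row[f"pct_{cls}"] = round(100.0 * n_cls / n_img, 1) if n_img else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
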