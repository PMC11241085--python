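"""Per-ear audiometric records, PTA sub-grouping, and distribution summaries.

The cohort model is one record per tested ear: a pure-tone average (PTA,
the mean air-conduction threshold at 0.5, 1, 2 and 4 kHz, in dB HL) and a
maximum speech identification score (PB_max, percent correct on a 25-item
monosyllable list, hence an integer multiple of 4). Ears with a conductive
component — an air-bone gap of 15 dB or more at two or more of 0.5/1/2 kHz —
are excluded, since the norms target sensorineural loss.

Sub-group schemes bin ears by PTA. Published bin labels such as "<15",
"16-25" leave nominal gaps; bins here are contiguous intervals with cut
points at label midpoints (15.5, 25.5, ...), so every PTA on the 1.25-dB
audiometric grid is assignable to exactly one bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EarRecord",
    "SubgroupScheme",
    "SubgroupSummary",
    "BUILTIN_SCHEMES",
    "compute_pta",
    "flag_conductive",
    "read_cohort",
    "assign_subgroup",
    "group_records",
    "summarize_subgroup",
    "round_to_step",
]

PTA_FREQS_KHZ = (0.5, 1.0, 2.0, 4.0)
AIR_BONE_GAP_FREQS_KHZ = (0.5, 1.0, 2.0)
AIR_BONE_GAP_DB = 15.0
SCORE_STEP = 4.0


@dataclass(frozen=True)
class EarRecord:
    """One tested ear: identifier, side, PTA (dB HL) and PB_max (% correct)."""

    participant_id: str
    ear: str  # "L" or "R"
    pta: float
    pbmax: float

    def __post_init__(self) -> None:
        if self.ear not in ("L", "R"):
            raise ValueError(f"ear must be 'L' or 'R', got {self.ear!r}")
        if not math.isfinite(self.pta):
            raise ValueError(f"non-finite PTA for participant {self.participant_id}")
        if not math.isfinite(self.pbmax) or not (0.0 <= self.pbmax <= 100.0):
            raise ValueError(
                f"PB_max must be finite and in [0, 100]; got {self.pbmax} "
                f"for participant {self.participant_id}"
            )


@dataclass(frozen=True)
class SubgroupScheme:
    """Ordered PTA bins.  Each bin is (lower, upper, label]; lower exclusive,
    upper inclusive, with the first lower bound at -inf so the scheme is total
    on non-negative PTA."""

    name: str
    bins: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        prev_hi = None
        for lo, hi, _label in self.bins:
            if not lo < hi:
                raise ValueError(f"empty bin ({lo}, {hi}] in scheme {self.name}")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError(
                    f"bins of scheme {self.name} must be contiguous and sorted; "
                    f"gap or overlap at {lo}"
                )
            prev_hi = hi

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, _, label in self.bins)

    @property
    def edges(self) -> np.ndarray:
        """Upper edges of the bins, for vectorized assignment."""
        return np.array([hi for _, hi, _ in self.bins])


def _scheme_from_cuts(name: str, cuts: Sequence[float], labels: Sequence[str]) -> SubgroupScheme:
    lows = (-math.inf, *cuts[:-1])
    return SubgroupScheme(name, tuple(zip(lows, cuts, labels)))


#: The four published sub-grouping criteria.  Cut points sit at the midpoints
#: of adjacent bin labels (e.g. "<15" | "16-25" cut at 15.5) so PTAs on the
#: 1.25-dB grid never fall in a nominal gap.  Identical for both ears.
BUILTIN_SCHEMES: dict[str, SubgroupScheme] = {
    "group1": _scheme_from_cuts(
        "group1",
        [15.5, 25.5, 35.5, 45.5, 55.5, 65.5, 75.5, 85.5, 120.0],
        ["<15", "16-25", "26-35", "36-45", "46-55", "56-65", "66-75", "76-85", "86-120"],
    ),
    "group2": _scheme_from_cuts(
        "group2",
        [10.5, 20.5, 30.5, 40.5, 50.5, 60.5, 70.5, 80.5, 120.0],
        ["<10", "11-20", "21-30", "31-40", "41-50", "51-60", "61-70", "71-80", "81-120"],
    ),
    "group3": _scheme_from_cuts(
        "group3",
        [10.5, 15.5, 20.5, 25.5, 30.5, 35.5, 40.5, 45.5, 50.5, 55.5, 60.5, 70.5, 80.5, 120.0],
        ["<10", "11-15", "16-20", "21-25", "26-30", "31-35", "36-40", "41-45",
         "46-50", "51-55", "56-60", "61-70", "71-80", "81-120"],
    ),
    "group4": _scheme_from_cuts(
        "group4",
        [15.5, 30.5, 45.5, 60.5, 75.5, 120.0],
        ["<15", "16-30", "31-45", "46-60", "61-75", "76-120"],
    ),
}


@dataclass
class SubgroupSummary:
    """Moments and quantile estimates of PB_max within one PTA bin.

    skewness is the third standardized moment and kurtosis the fourth
    (non-excess: a normal law gives 3).  Zero-variance bins report NaN for
    both.  cl_value / cl_se are filled in by the estimation methods.
    """

    label: str
    n: int
    mean_pta: float
    mean_pbmax: float
    sd_pbmax: float
    skewness: float = math.nan
    kurtosis: float = math.nan
    median_pbmax: float = math.nan
    cl_value: float = math.nan
    cl_se: float = math.nan
    extra: dict = field(default_factory=dict)


def compute_pta(htl_500: float, htl_1000: float, htl_2000: float, htl_4000: float) -> float:
    """Pure-tone average: arithmetic mean of the air-conduction thresholds at
    0.5, 1, 2 and 4 kHz (dB HL)."""
    vals = (htl_500, htl_1000, htl_2000, htl_4000)
    if not all(isinstance(v, (int, float)) and math.isfinite(v) for v in vals):
        raise ValueError(f"all four thresholds must be finite, got {vals}")
    return float(sum(vals)) / 4.0


def flag_conductive(
    air_htls: dict[float, float], bone_htls: dict[float, float] | None
) -> bool:
    """True iff the air-bone gap is >= 15 dB at two or more of 0.5, 1, 2 kHz.

    Flagged ears carry a conductive component and are excluded.  If bone
    thresholds are unavailable the rule cannot be applied; the ear passes
    with a warning.
    """
    if not bone_htls:
        logger.warning("bone-conduction thresholds absent; conductive-loss rule not applied")
        return False
    missing = [f for f in AIR_BONE_GAP_FREQS_KHZ if f not in air_htls or f not in bone_htls]
    if missing:
        raise ValueError(f"air/bone thresholds required at {AIR_BONE_GAP_FREQS_KHZ}; missing {missing}")
    n_gaps = sum(
        1
        for f in AIR_BONE_GAP_FREQS_KHZ
        if air_htls[f] - bone_htls[f] >= AIR_BONE_GAP_DB
    )
    return n_gaps >= 2


def round_to_step(value: float, step: float = SCORE_STEP) -> float:
    """Round to the nearest integer multiple of ``step``; exact halves round
    away from zero (so 86.0 with step 4 -> 88)."""
    if step <= 0:
        raise ValueError("step must be positive")
    v = np.asarray(value, dtype=float)
    out = np.sign(v) * np.floor(np.abs(v) / step + 0.5) * step
    if np.ndim(value) == 0:
        return float(out)
    return out


_AIR_COLS = ["htl_500", "htl_1000", "htl_2000", "htl_4000"]
_BONE_COLS = {"bone_500": 0.5, "bone_1000": 1.0, "bone_2000": 2.0}


def read_cohort(path, *, strict_step: bool = False) -> list[EarRecord]:
    """Read per-ear records from CSV and validate them.

    Canonical columns: participant_id, ear (L/R), pbmax, and either a ``pta``
    column or the four air-conduction threshold columns htl_500..htl_4000.
    Optional bone_500/bone_1000/bone_2000 columns trigger the conductive-loss
    exclusion.  Rows violating the record invariants are rejected with their
    line numbers; PB_max values off the 4-point grid are warned about (or
    rejected when ``strict_step``), since scores from 25-item lists must be
    multiples of 4.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "ear", "pbmax"}
    if missing := required - set(df.columns):
        raise ValueError(f"cohort file {path} missing columns: {sorted(missing)}")
    has_pta = "pta" in df.columns
    if not has_pta and not all(c in df.columns for c in _AIR_COLS):
        raise ValueError(
            f"cohort file {path} needs a 'pta' column or all of {_AIR_COLS}"
        )
    bone_cols = [c for c in _BONE_COLS if c in df.columns]

    records: list[EarRecord] = []
    errors: list[str] = []
    n_excluded = 0
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            if has_pta and pd.notna(row.get("pta")):
                pta = float(row["pta"])
            else:
                pta = compute_pta(*(float(row[c]) for c in _AIR_COLS))
            pbmax = float(row["pbmax"])
            if pd.isna(pbmax) or pd.isna(pta):
                raise ValueError("missing pta or pbmax")
            has_air = all(c in df.columns and pd.notna(row[c]) for c in _AIR_COLS[:3])
            bone = {_BONE_COLS[c]: float(row[c]) for c in bone_cols if pd.notna(row[c])}
            if has_air and len(bone) == len(_BONE_COLS):
                air = {0.5: float(row["htl_500"]), 1.0: float(row["htl_1000"]),
                       2.0: float(row["htl_2000"])}
                if flag_conductive(air, bone):
                    n_excluded += 1
                    continue
            off_grid = abs(pbmax - round_to_step(pbmax)) > 1e-9
            if off_grid:
                msg = f"line {line}: pbmax {pbmax} is not a multiple of {SCORE_STEP:g}"
                if strict_step:
                    raise ValueError(msg)
                logger.warning(msg)
            records.append(
                EarRecord(str(row["participant_id"]), str(row["ear"]).upper(), pta, pbmax)
            )
        except (ValueError, TypeError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(
            f"{len(errors)} invalid row(s) in {path}:\n  " + "\n  ".join(errors)
        )
    if n_excluded:
        logger.info("excluded %d ear(s) with a conductive component", n_excluded)
    return records


def assign_subgroup(record: EarRecord, scheme: SubgroupScheme) -> str:
    """Label of the unique scheme bin containing ``record.pta``."""
    for lo, hi, label in scheme.bins:
        if lo < record.pta <= hi:
            return label
    raise ValueError(
        f"PTA {record.pta} of participant {record.participant_id} falls outside "
        f"all bins of scheme {scheme.name} (max edge {scheme.bins[-1][1]})"
    )


def group_records(
    records: Iterable[EarRecord], scheme: SubgroupScheme
) -> dict[str, list[EarRecord]]:
    """Partition records by scheme bin, preserving bin order; every record is
    assigned exactly once."""
    groups: dict[str, list[EarRecord]] = {label: [] for label in scheme.labels}
    for rec in records:
        groups[assign_subgroup(rec, scheme)].append(rec)
    return groups


def summarize_subgroup(records: Sequence[EarRecord], label: str = "") -> SubgroupSummary:
    """Moments of PB_max within one bin: mean, sample SD (n-1), third and
    fourth standardized moments (kurtosis non-excess), and the plain median."""
    if not records:
        raise ValueError("cannot summarize an empty sub-group")
    scores = np.array([r.pbmax for r in records], dtype=float)
    ptas = np.array([r.pta for r in records], dtype=float)
    n = len(records)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if n >= 2 else math.nan
    if n >= 3 and sd > 0:
        skew = float(stats.skew(scores, bias=True))
        kurt = float(stats.kurtosis(scores, fisher=False, bias=True))
    else:
        skew = kurt = math.nan  # undefined for tiny or zero-variance bins
    return SubgroupSummary(
        label=label,
        n=n,
        mean_pta=float(ptas.mean()),
        mean_pbmax=mean,
        sd_pbmax=sd if n >= 2 else math.nan,
        skewness=skew,
        kurtosis=kurt,
        median_pbmax=float(np.median(scores)),
    )
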