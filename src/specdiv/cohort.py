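"""Residue-level mismatch risk estimation for an HLA-C-mismatched cohort.

Each patient-donor pair is reduced to its set of mismatched residues and a
binary death outcome. Per unoriented mismatch the pipeline computes
oriented mortality rates, a max-symmetrized rate, an allele-pair-capped
subsampling-adjusted rate (to debias mismatches dominated by one common
allele pair), the mortality rate of the complement, and their ratio
(relative risk). Mismatches are kept only when both oriented counts clear
a high-counts threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .profiles import ALPHABET
from .util import UndefinedResultError, derive_seed

SEVERITIES = ("low", "intermediate", "high")


class OrientedMismatch(NamedTuple):
    position: int  # 1-based over the alignment
    patient_res: str
    donor_res: str


class UnorientedMismatch(NamedTuple):
    position: int
    res_a: str  # alphabetically first
    res_b: str

    @classmethod
    def of(cls, position: int, r1: str, r2: str) -> "UnorientedMismatch":
        if r1 == r2:
            raise ValueError(f"not a mismatch: {r1}/{r2} at {position}")
        a, b = sorted((r1, r2))
        return cls(position, a, b)


@dataclass(frozen=True)
class TransplantPair:
    """One 9/10-matched pair: single mismatched HLA-C allele, binary outcome."""

    pair_id: str
    patient_allele: str
    donor_allele: str
    patient_seq: str
    donor_seq: str
    death: int  # 1 = died
    severity: str

    def __post_init__(self) -> None:
        if len(self.patient_seq) != len(self.donor_seq):
            raise ValueError(f"{self.pair_id}: sequences have unequal length")
        if self.patient_seq == self.donor_seq:
            raise ValueError(f"{self.pair_id}: sequences are identical (matched pair)")
        if self.death not in (0, 1):
            raise ValueError(f"{self.pair_id}: death must be 0 or 1")
        if self.severity not in SEVERITIES:
            raise ValueError(
                f"{self.pair_id}: unknown severity {self.severity!r} "
                f"(expected one of {SEVERITIES})"
            )

    @property
    def allele_pair(self) -> tuple[str, str]:
        """Unordered allele-level pair key (patient/donor roles ignored)."""
        return tuple(sorted((self.patient_allele, self.donor_allele)))

    def mismatches(self) -> list[OrientedMismatch]:
        return extract_mismatches(self.patient_seq, self.donor_seq)


@dataclass
class OrientationTally:
    """Pairs carrying one orientation of a mismatch, grouped by allele pair."""

    pair_ids: list[str] = field(default_factory=list)
    deaths: int = 0
    # unordered allele pair -> death indicators of contributing pairs
    groups: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.pair_ids)

    @property
    def rate(self) -> float:
        if self.count == 0:
            raise UndefinedResultError("mortality rate over zero pairs")
        return self.deaths / self.count

    def add(self, pair: TransplantPair) -> None:
        self.pair_ids.append(pair.pair_id)
        self.deaths += pair.death
        self.groups.setdefault(pair.allele_pair, []).append(pair.death)


@dataclass
class MismatchTally:
    """Both orientations of one unoriented mismatch."""

    mismatch: UnorientedMismatch
    # orientation key: (patient_res, donor_res)
    orientations: dict[tuple[str, str], OrientationTally] = field(default_factory=dict)

    def orientation(self, patient_res: str, donor_res: str) -> OrientationTally:
        return self.orientations.get((patient_res, donor_res), OrientationTally())

    @property
    def oriented_counts(self) -> tuple[int, int]:
        """Counts in (res_a-as-patient, res_b-as-patient) order."""
        m = self.mismatch
        return (
            self.orientation(m.res_a, m.res_b).count,
            self.orientation(m.res_b, m.res_a).count,
        )

    @property
    def total_count(self) -> int:
        return sum(self.oriented_counts)

    @property
    def carrier_pair_ids(self) -> set[str]:
        return {
            pid for t in self.orientations.values() for pid in t.pair_ids
        }

    @property
    def carrier_deaths(self) -> int:
        return sum(t.deaths for t in self.orientations.values())


@dataclass(frozen=True)
class RiskConfig:
    high_counts_threshold: int = 100
    subsample_cap: int = 10
    subsample_reps: int = 1000
    seed: int = 0
    exclude_severities: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("high_counts_threshold", "subsample_cap", "subsample_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        unknown = set(self.exclude_severities) - set(SEVERITIES)
        if unknown:
            raise ValueError(f"unknown severity levels {sorted(unknown)}")


@dataclass(frozen=True)
class RiskRecord:
    """Risk summary for one unoriented mismatch.

    Orientation 1 has the alphabetically first residue on the patient side.
    Absent orientations and undefined ratios are carried as None.
    """

    mismatch: UnorientedMismatch
    count_or1: int
    count_or2: int
    rate_oriented_1: float | None
    rate_oriented_2: float | None
    rate_symmetrized: float
    rate_adjusted: float
    rate_complement: float | None
    relative_risk: float | None
    high_counts: bool


def extract_mismatches(patient_seq: str, donor_seq: str) -> list[OrientedMismatch]:
    """Oriented residue mismatches between two aligned sequences, by position."""
    if len(patient_seq) != len(donor_seq):
        raise ValueError("aligned sequences must have equal length")
    return [
        OrientedMismatch(i + 1, p, d)
        for i, (p, d) in enumerate(zip(patient_seq, donor_seq))
        if p != d
    ]


def tally_mismatches(
    cohort: list[TransplantPair],
) -> dict[UnorientedMismatch, MismatchTally]:
    """Tally every pair into every mismatch it carries.

    Mismatch sets are cached per (patient_seq, donor_seq) since synthetic
    cohorts repeat allele pairs heavily.
    """
    tallies: dict[UnorientedMismatch, MismatchTally] = {}
    cache: dict[tuple[str, str], list[OrientedMismatch]] = {}
    for pair in cohort:
        key = (pair.patient_seq, pair.donor_seq)
        mms = cache.get(key)
        if mms is None:
            mms = pair.mismatches()
            cache[key] = mms
        for mm in mms:
            um = UnorientedMismatch.of(mm.position, mm.patient_res, mm.donor_res)
            tally = tallies.setdefault(um, MismatchTally(mismatch=um))
            orient = tally.orientations.setdefault(
                (mm.patient_res, mm.donor_res), OrientationTally()
            )
            orient.add(pair)
    return tallies


def symmetrized_rate(tally: MismatchTally) -> float:
    """Max over nonempty orientations of deaths/count."""
    rates = [t.rate for t in tally.orientations.values() if t.count > 0]
    if not rates:
        raise UndefinedResultError(
            f"no pairs carry mismatch {tally.mismatch}; rate undefined"
        )
    return max(rates)


def _adjusted_orientation_rate(
    orient: OrientationTally, cap: int, reps: int, rng: np.random.Generator
) -> float:
    """Mean over replicates of the capped-subsample mortality rate.

    Drawing ``min(cap, g)`` pairs without replacement from a group with
    ``d`` deaths among ``g`` pairs makes the drawn death count
    hypergeometric; sampling that count directly is distributionally
    identical to subsampling the pairs.
    """
    n_drawn = 0
    deaths = np.zeros(reps)
    for key in sorted(orient.groups):
        outcomes = orient.groups[key]
        g = len(outcomes)
        d = sum(outcomes)
        k = min(cap, g)
        n_drawn += k
        if k == g:
            deaths += d
        else:
            deaths += rng.hypergeometric(d, g - d, k, size=reps)
    return float((deaths / n_drawn).mean())


def subsampled_rate(
    tally: MismatchTally, cap: int, reps: int, seed: int
) -> float:
    """Allele-pair-capped subsampling-adjusted rate, symmetrized by max.

    Per orientation: in each replicate draw at most ``cap`` pairs from every
    allele-pair group (all of them when the group is smaller), compute the
    mortality rate of the drawn pairs, and average over ``reps`` replicates.
    The adjusted oriented rates are then symmetrized by taking the maximum.
    """
    if cap < 1 or reps < 1:
        raise ValueError("cap and reps must be at least 1")
    rng = np.random.default_rng(seed)
    rates = []
    for key in sorted(tally.orientations):
        orient = tally.orientations[key]
        if orient.count > 0:
            rates.append(_adjusted_orientation_rate(orient, cap, reps, rng))
    if not rates:
        raise UndefinedResultError(
            f"no pairs carry mismatch {tally.mismatch}; adjusted rate undefined"
        )
    return max(rates)


def _record_from_tally(
    tally: MismatchTally,
    n_cohort: int,
    total_deaths: int,
    config: RiskConfig,
    rate_mode: str,
) -> RiskRecord:
    m = tally.mismatch
    or1 = tally.orientation(m.res_a, m.res_b)
    or2 = tally.orientation(m.res_b, m.res_a)
    rate1 = or1.rate if or1.count else None
    rate2 = or2.rate if or2.count else None
    rate_sym = symmetrized_rate(tally)
    rate_adj = subsampled_rate(
        tally,
        config.subsample_cap,
        config.subsample_reps,
        derive_seed(config.seed, "subsample", f"{m.position}:{m.res_a}:{m.res_b}"),
    )
    n_comp = n_cohort - len(tally.carrier_pair_ids)
    d_comp = total_deaths - tally.carrier_deaths
    rate_comp = d_comp / n_comp if n_comp > 0 else None
    numerator = rate_adj if rate_mode == "adjusted" else rate_sym
    rr = None
    if rate_comp is not None and rate_comp > 0:
        rr = numerator / rate_comp
    return RiskRecord(
        mismatch=m,
        count_or1=or1.count,
        count_or2=or2.count,
        rate_oriented_1=rate1,
        rate_oriented_2=rate2,
        rate_symmetrized=rate_sym,
        rate_adjusted=rate_adj,
        rate_complement=rate_comp,
        relative_risk=rr,
        high_counts=min(or1.count, or2.count) >= config.high_counts_threshold,
    )


def relative_risk(
    mismatch: UnorientedMismatch,
    cohort: list[TransplantPair],
    config: RiskConfig,
    rate_mode: str = "adjusted",
) -> RiskRecord:
    """Risk record for one mismatch against the rest of the cohort.

    Numerator: symmetrized (raw) or subsampling-adjusted rate of the
    mismatch carriers. Denominator: mortality rate of all cohort pairs not
    carrying the unoriented mismatch in either orientation. The ratio is
    None (undefined) when the complement is empty or its rate is zero.
    """
    if rate_mode not in ("raw", "adjusted"):
        raise ValueError(f"unknown rate_mode {rate_mode!r}")
    tallies = tally_mismatches(cohort)
    if mismatch not in tallies:
        raise ValueError(f"mismatch {mismatch} not present in cohort")
    total_deaths = sum(p.death for p in cohort)
    return _record_from_tally(
        tallies[mismatch], len(cohort), total_deaths, config, rate_mode
    )


def high_counts_filter(
    tallies: dict[UnorientedMismatch, MismatchTally], threshold: int
) -> dict[UnorientedMismatch, MismatchTally]:
    """Keep mismatches whose BOTH oriented counts reach the threshold."""
    if threshold < 1:
        raise ValueError("threshold must be at least 1")
    return {
        um: t
        for um, t in tallies.items()
        if min(t.oriented_counts) >= threshold
    }


def stratify_by_severity(
    cohort: list[TransplantPair], exclude: set[str]
) -> list[TransplantPair]:
    """Drop pairs whose severity class is in ``exclude``."""
    unknown = set(exclude) - set(SEVERITIES)
    if unknown:
        raise ValueError(f"unknown severity levels {sorted(unknown)}")
    return [p for p in cohort if p.severity not in exclude]


def run_risk_pipeline(
    cohort: list[TransplantPair],
    config: RiskConfig,
    rate_mode: str = "adjusted",
) -> list[RiskRecord]:
    """Severity filter -> tally -> high-counts filter -> rates -> risks.

    Returns one record per kept mismatch, sorted by (position, residues);
    deterministic per config seed.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if rate_mode not in ("raw", "adjusted"):
        raise ValueError(f"unknown rate_mode {rate_mode!r}")
    kept_cohort = stratify_by_severity(cohort, set(config.exclude_severities))
    if not kept_cohort:
        raise UndefinedResultError("severity filter removed every pair")
    tallies = tally_mismatches(kept_cohort)
    kept = high_counts_filter(tallies, config.high_counts_threshold)
    total_deaths = sum(p.death for p in kept_cohort)
    records = [
        _record_from_tally(kept[um], len(kept_cohort), total_deaths, config, rate_mode)
        for um in sorted(kept)
    ]
    return records


def risk_table(records: list[RiskRecord]) -> pd.DataFrame:
    """Risk records as a flat table (None -> NaN)."""
    rows = []
    for r in records:
        rows.append(
            {
                "position": r.mismatch.position,
                "res_a": r.mismatch.res_a,
                "res_b": r.mismatch.res_b,
                "count_or1": r.count_or1,
                "count_or2": r.count_or2,
                "rate_or1": np.nan if r.rate_oriented_1 is None else r.rate_oriented_1,
                "rate_or2": np.nan if r.rate_oriented_2 is None else r.rate_oriented_2,
                "rate_symmetrized": r.rate_symmetrized,
                "rate_adjusted": r.rate_adjusted,
                "rate_complement": (
                    np.nan if r.rate_complement is None else r.rate_complement
                ),
                "relative_risk": np.nan if r.relative_risk is None else r.relative_risk,
                "high_counts": r.high_counts,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "res_a", "res_b", "count_or1", "count_or2",
            "rate_or1", "rate_or2", "rate_symmetrized", "rate_adjusted",
            "rate_complement", "relative_risk", "high_counts",
        ],
    )


def validate_residue(res: str) -> str:
    if res not in set(ALPHABET):
        raise ValueError(f"{res!r} is not an amino acid")
    return res
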