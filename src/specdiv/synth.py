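"""Synthetic data generators: allele pools, ground-truth divergences,
survival cohorts, controlled PFM perturbation pairs, and a toy
peptide-receptor structure.

Everything is deterministic per seed so the full pipeline can be exercised
and parameter-recovery tested without external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .cohort import SEVERITIES, TransplantPair, UnorientedMismatch, extract_mismatches
from .mc import HlaSequence
from .profiles import ALPHABET, N_AA, PEPTIDE_LENGTH, BindingProfile


@dataclass(frozen=True)
class AllelePool:
    """Synthetic alleles differing from a base sequence at fixed sites."""

    alleles: tuple[HlaSequence, ...]
    polymorphic_positions: tuple[int, ...]  # 1-based
    base_sequence: str

    def by_label(self, label: str) -> HlaSequence:
        for a in self.alleles:
            if a.allele == label:
                return a
        raise KeyError(f"allele {label!r} not in pool")

    def distinct_pairs(self) -> list[tuple[HlaSequence, HlaSequence]]:
        """Unordered allele pairs whose sequences actually differ."""
        return [
            (a, b)
            for a, b in itertools.combinations(self.alleles, 2)
            if a.residues != b.residues
        ]


@dataclass(frozen=True)
class GroundTruth:
    """True per-mismatch specificity divergences used to generate outcomes."""

    delta: dict[UnorientedMismatch, float]

    def mismatch_divergence(self, mismatch: UnorientedMismatch) -> float:
        return self.delta.get(mismatch, 0.0)

    def pair_divergence(self, seq_a: str, seq_b: str) -> float:
        """Sum of per-mismatch divergences over the pair's mismatched sites."""
        total = 0.0
        for mm in extract_mismatches(seq_a, seq_b):
            total += self.mismatch_divergence(
                UnorientedMismatch.of(mm.position, mm.patient_res, mm.donor_res)
            )
        return total


@dataclass(frozen=True)
class CohortModel:
    """Generative model for a synthetic transplant cohort.

    Death is Bernoulli with log-odds
    ``beta0 + beta_div * D + beta_high * 1[severity == high]`` where D is
    the pair's true total divergence. ``allele_pair_weights`` maps
    unordered label pairs to sampling weights (None = uniform over all
    distinct-sequence pairs).
    """

    n_pairs: int
    beta0: float = 0.0
    beta_div: float = 0.0
    beta_high: float = 0.0
    severity_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    allele_pair_weights: dict[tuple[str, str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be at least 1")
        sp = np.asarray(self.severity_probs, dtype=float)
        if sp.shape != (3,) or (sp < 0).any() or abs(sp.sum() - 1) > 1e-9:
            raise ValueError("severity_probs must be 3 nonnegative values summing to 1")
        if self.allele_pair_weights is not None:
            w = list(self.allele_pair_weights.values())
            if any(x < 0 for x in w):
                raise ValueError("allele pair weights must be nonnegative")


def generate_allele_pool(
    n_alleles: int,
    seq_length: int,
    n_polymorphic: int,
    residues_per_site: int,
    seed: int,
) -> AllelePool:
    """Random base sequence plus alleles varying at fixed polymorphic sites."""
    if not 0 <= n_polymorphic <= seq_length:
        raise ValueError("n_polymorphic must lie in [0, seq_length]")
    if not 2 <= residues_per_site <= N_AA:
        raise ValueError("residues_per_site must lie in [2, 20]")
    if n_alleles < 1:
        raise ValueError("n_alleles must be at least 1")
    rng = np.random.default_rng(seed)
    aas = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    base = bytes(aas[rng.integers(0, N_AA, seq_length)]).decode("ascii")
    positions = tuple(
        sorted(int(p) + 1 for p in rng.choice(seq_length, n_polymorphic, replace=False))
    )
    site_residues = {
        p: [ALPHABET[i] for i in rng.choice(N_AA, residues_per_site, replace=False)]
        for p in positions
    }
    alleles = []
    for i in range(n_alleles):
        seq = list(base)
        for p in positions:
            seq[p - 1] = site_residues[p][rng.integers(0, residues_per_site)]
        alleles.append(HlaSequence(allele=f"SYN*{i + 1:03d}", residues="".join(seq)))
    return AllelePool(
        alleles=tuple(alleles),
        polymorphic_positions=positions,
        base_sequence=base,
    )


def assign_ground_truth(
    pool: AllelePool, mean_delta: float, frac_null: float, seed: int
) -> GroundTruth:
    """Assign each realized mismatch a true divergence.

    With probability ``frac_null`` the divergence is 0 (a permissive
    mismatch); otherwise it is Exponential with mean ``mean_delta``.
    """
    if mean_delta <= 0:
        raise ValueError("mean_delta must be positive")
    if not 0 <= frac_null <= 1:
        raise ValueError("frac_null must lie in [0, 1]")
    realized: set[UnorientedMismatch] = set()
    for a, b in pool.distinct_pairs():
        for mm in extract_mismatches(a.residues, b.residues):
            realized.add(UnorientedMismatch.of(mm.position, mm.patient_res, mm.donor_res))
    rng = np.random.default_rng(seed)
    delta = {}
    for um in sorted(realized):
        if rng.random() < frac_null:
            delta[um] = 0.0
        else:
            delta[um] = float(rng.exponential(mean_delta))
    return GroundTruth(delta=delta)


def skewed_pair_weights(
    pool: AllelePool, concentration: float, seed: int
) -> dict[tuple[str, str], float]:
    """Dirichlet weights over distinct allele pairs; small concentration
    values produce the skewed pair frequencies that exercise debiasing."""
    pairs = pool.distinct_pairs()
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(len(pairs), concentration))
    return {
        tuple(sorted((a.allele, b.allele))): float(x)
        for (a, b), x in zip(pairs, w)
    }


def generate_cohort(
    pool: AllelePool, truth: GroundTruth, model: CohortModel
) -> list[TransplantPair]:
    """Draw a synthetic cohort of mismatched pairs with survival outcomes."""
    pairs = pool.distinct_pairs()
    if len(pool.alleles) < 2 or not pairs:
        raise ValueError("pool must contain at least 2 distinct alleles")
    if model.allele_pair_weights is None:
        weights = np.ones(len(pairs))
    else:
        weights = np.array(
            [
                model.allele_pair_weights.get(
                    tuple(sorted((a.allele, b.allele))), 0.0
                )
                for a, b in pairs
            ]
        )
    if weights.sum() <= 0:
        raise ValueError("allele pair weights are all zero over the pool")
    weights = weights / weights.sum()

    div = np.array([truth.pair_divergence(a.residues, b.residues) for a, b in pairs])
    rng = np.random.default_rng(model.seed)
    n = model.n_pairs
    pair_idx = rng.choice(len(pairs), size=n, p=weights)
    orient = rng.integers(0, 2, size=n)
    severity_idx = rng.choice(3, size=n, p=np.asarray(model.severity_probs))
    logit = (
        model.beta0
        + model.beta_div * div[pair_idx]
        + model.beta_high * (severity_idx == 2)
    )
    death = (rng.random(n) < expit(logit)).astype(int)

    cohort = []
    for i in range(n):
        a, b = pairs[pair_idx[i]]
        patient, donor = (a, b) if orient[i] == 0 else (b, a)
        cohort.append(
            TransplantPair(
                pair_id=f"P{i + 1:05d}",
                patient_allele=patient.allele,
                donor_allele=donor.allele,
                patient_seq=patient.residues,
                donor_seq=donor.residues,
                death=int(death[i]),
                severity=SEVERITIES[severity_idx[i]],
            )
        )
    return cohort


def generate_pfm_pair(
    base_profile: BindingProfile,
    positions: list[int],
    epsilon: float,
    seed: int,
) -> tuple[BindingProfile, BindingProfile]:
    """Perturb selected columns of a profile by mixing toward random columns.

    The second profile's selected columns are
    ``(1 - epsilon) * base + epsilon * Dirichlet(1, ..., 1)``; with a fixed
    seed the random target columns are identical across epsilon values, so
    divergence grows monotonically with epsilon.
    """
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must lie in [0, 1]")
    for p in positions:
        if not 1 <= p <= PEPTIDE_LENGTH:
            raise ValueError(f"peptide position {p} outside 1..9")
    rng = np.random.default_rng(seed)
    freqs = base_profile.freqs.copy()
    for p in sorted(set(positions)):
        target = rng.dirichlet(np.ones(N_AA))
        freqs[p - 1] = (1 - epsilon) * base_profile.freqs[p - 1] + epsilon * target
    a = BindingProfile(label=base_profile.label, freqs=base_profile.freqs.copy())
    b = BindingProfile(label=f"{base_profile.label}_eps{epsilon:g}", freqs=freqs)
    return a, b


# ---------------------------------------------------------------------------
# Toy structure
# ---------------------------------------------------------------------------

#: Designed contacts of the toy structure: HLA residue number -> peptide
#: position it sits next to (within 4.5 A; every other HLA residue is far).
TOY_CONTACTS = {9: 2, 3: 5, 11: 9}
TOY_PEPTIDE_CHAIN = "P"
TOY_HLA_CHAIN = "A"
TOY_N_HLA_RESIDUES = 12


def _atom_line(serial, name, resname, chain, resnum, x, y, z, element) -> str:
    return (
        f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def generate_toy_structure(seed: int = 0) -> str:
    """PDB-format text with a 9-residue peptide chain and 12 receptor residues.

    The peptide lies along the x axis (CA spacing 3.8 A). Receptor residues
    named in :data:`TOY_CONTACTS` sit 3.0-3.5 A from their peptide partner's
    CA; all others are placed far away (> 10 A, positions jittered by the
    seed). Each residue carries CA and O heavy atoms.
    """
    rng = np.random.default_rng(seed)
    lines = ["HEADER    TOY PEPTIDE-RECEPTOR COMPLEX"]
    serial = 1

    def residue(chain, resnum, x, y, z):
        nonlocal serial
        lines.append(_atom_line(serial, "CA", "GLY", chain, resnum, x, y, z, "C"))
        serial += 1
        lines.append(_atom_line(serial, "O", "GLY", chain, resnum, x, y, z + 1.2, "O"))
        serial += 1

    for i in range(PEPTIDE_LENGTH):
        residue(TOY_PEPTIDE_CHAIN, i + 1, 3.8 * i, 0.0, 0.0)
    for h in range(1, TOY_N_HLA_RESIDUES + 1):
        if h in TOY_CONTACTS:
            pep = TOY_CONTACTS[h]
            dist = 3.0 if h != 3 else 3.5
            residue(TOY_HLA_CHAIN, h, 3.8 * (pep - 1), dist, 0.0)
        else:
            residue(
                TOY_HLA_CHAIN,
                h,
                float(rng.uniform(-20, 50)),
                float(rng.uniform(40, 60)),
                float(rng.uniform(-20, 20)),
            )
    lines.append("END")
    return "\n".join(lines) + "\n"
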