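"""Metropolis Monte Carlo sampler over peptide sequences.

A desk-scale stand-in for flexible-backbone docking: the receptor backbone
is frozen into a contact map (which peptide positions touch which receptor
residues, with weights), the energetics are a symmetric 20x20 residue
interaction matrix, and the only degrees of freedom are the peptide's nine
residues. Many short independent chains are run; the final sequence of each
chain is kept and compiled into a binding profile.

Because the energy is additive over peptide positions, the stationary
distribution factorizes into independent per-position Boltzmann
distributions (:func:`stationary_distribution`), which gives an exact
oracle for validating the sampler.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace

import numpy as np
from Bio.PDB import PDBParser

from .profiles import (
    AA_INDEX,
    ALPHABET,
    N_AA,
    PEPTIDE_LENGTH,
    BindingProfile,
    DivergenceResult,
    compile_pfm,
    profile_divergence,
)
from .util import derive_seed


@dataclass(frozen=True)
class HlaSequence:
    """An HLA protein sequence with 1-based mature-protein numbering."""

    allele: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(f"{self.allele}: non-alphabet residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise ValueError(
                f"position {position} outside sequence of length {len(self.residues)}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class ContactMap:
    """Weighted contacts between peptide positions 1..9 and HLA residues.

    ``contacts[p]`` (0-based peptide index) is a list of
    ``(hla_position, weight)`` with 1-based HLA positions and nonnegative
    weights; nonempty positions have weights summing to 1.
    """

    contacts: tuple[tuple[tuple[int, float], ...], ...]

    def __post_init__(self) -> None:
        if len(self.contacts) != PEPTIDE_LENGTH:
            raise ValueError("contact map must cover all 9 peptide positions")
        for p, entries in enumerate(self.contacts):
            for h, w in entries:
                if h < 1:
                    raise ValueError(f"peptide position {p + 1}: HLA position {h} < 1")
                if w < 0:
                    raise ValueError(f"peptide position {p + 1}: negative weight")

    @property
    def max_hla_position(self) -> int:
        return max((h for entries in self.contacts for h, _ in entries), default=0)

    @classmethod
    def from_dict(cls, mapping: dict[int, list[tuple[int, float]]]) -> "ContactMap":
        """Build from ``{peptide_position (1-based): [(hla_pos, weight), ...]}``."""
        contacts = tuple(
            tuple(mapping.get(p, [])) for p in range(1, PEPTIDE_LENGTH + 1)
        )
        return cls(contacts=contacts)


@dataclass(frozen=True)
class InteractionModel:
    """Symmetric 20x20 residue-residue interaction energies in kT."""

    energy: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy, dtype=float)
        if e.shape != (N_AA, N_AA):
            raise ValueError("energy matrix must be 20x20")
        if not np.isfinite(e).all():
            raise ValueError("energy matrix must be finite")
        if not np.allclose(e, e.T, atol=1e-12):
            raise ValueError("energy matrix must be symmetric")
        object.__setattr__(self, "energy", e)

    def e(self, a: str, b: str) -> float:
        return float(self.energy[AA_INDEX[a], AA_INDEX[b]])


@dataclass(frozen=True)
class SimulatorConfig:
    n_runs: int = 2000
    n_steps: int = 200
    temperature: float = 1.0
    seed: int = 0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")


@dataclass(frozen=True)
class SimulationResult:
    final_peptides: list[str]
    profile: BindingProfile
    acceptance_rate: float | None  # None when no proposals were made


# Kyte-Doolittle hydropathy index.
_KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


def default_interaction_model(w_h: float = 1.0, w_q: float = 1.0) -> InteractionModel:
    """Hydropathy-attraction plus like-charge-repulsion energetics.

    ``e(a, b) = -w_h * h(a) * h(b) + w_q * q(a) * q(b)`` where ``h`` is the
    Kyte-Doolittle hydropathy rescaled linearly to [-1, 1] and ``q`` is the
    formal side-chain charge at neutral pH (D, E = -1; K, R = +1; else 0).
    """
    h = np.array([_KYTE_DOOLITTLE[aa] for aa in ALPHABET])
    hmin, hmax = h.min(), h.max()
    h_scaled = 2 * (h - hmin) / (hmax - hmin) - 1
    q = np.array([_CHARGE.get(aa, 0.0) for aa in ALPHABET])
    energy = -w_h * np.outer(h_scaled, h_scaled) + w_q * np.outer(q, q)
    return InteractionModel(energy=energy)


def build_contact_map(
    structure: str,
    hla_chain: str,
    peptide_chain: str,
    cutoff: float = 4.5,
    weighting: str = "binary",
) -> ContactMap:
    """Derive a contact map from PDB-format text.

    A peptide position contacts an HLA residue iff any heavy-atom pair is
    within ``cutoff`` angstroms; weights are 1 per contact ("binary") or
    the number of qualifying atom pairs ("atom_count"), then normalized so
    each nonempty peptide position's weights sum to 1.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if weighting not in ("binary", "atom_count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", _io.StringIO(structure))[0]
    chain_ids = [c.id for c in model]
    for cid in (hla_chain, peptide_chain):
        if cid not in chain_ids:
            raise ValueError(f"chain {cid!r} not found (have {chain_ids})")

    def heavy_coords(chain):
        out = []
        for res in chain:
            coords = np.array(
                [a.coord for a in res if a.element != "H"], dtype=float
            )
            if len(coords):
                out.append((res.id[1], coords))
        return out

    pep = heavy_coords(model[peptide_chain])
    hla = heavy_coords(model[hla_chain])
    if len(pep) != PEPTIDE_LENGTH:
        raise ValueError(
            f"peptide chain {peptide_chain!r} has {len(pep)} residues, expected 9"
        )
    pep.sort(key=lambda t: t[0])

    mapping: dict[int, list[tuple[int, float]]] = {}
    for p, (_, pc) in enumerate(pep, start=1):
        entries = []
        for hnum, hc in hla:
            d2 = ((pc[:, None, :] - hc[None, :, :]) ** 2).sum(axis=2)
            n_close = int((d2 <= cutoff * cutoff).sum())
            if n_close:
                entries.append((hnum, 1.0 if weighting == "binary" else float(n_close)))
        if entries:
            total = sum(w for _, w in entries)
            entries = [(h, w / total) for h, w in entries]
            mapping[p] = entries
    return ContactMap.from_dict(mapping)


def position_energy_table(
    hla: HlaSequence, cmap: ContactMap, model: InteractionModel
) -> np.ndarray:
    """(9, 20) table: energy contribution of residue ``a`` at peptide
    position ``p`` given the fixed HLA sequence.

    ``table[p, a] = sum over (h, w) in cmap[p] of w * e(a, hla[h])``.
    """
    if cmap.max_hla_position > len(hla):
        raise ValueError(
            f"contact map references HLA position {cmap.max_hla_position} "
            f"beyond sequence length {len(hla)}"
        )
    table = np.zeros((PEPTIDE_LENGTH, N_AA))
    for p, entries in enumerate(cmap.contacts):
        for h, w in entries:
            table[p] += w * model.energy[:, AA_INDEX[hla.residues[h - 1]]]
    return table


def peptide_energy(
    hla: HlaSequence, cmap: ContactMap, model: InteractionModel, peptide: str
) -> float:
    """Total contact-map energy of a bound 9-mer, in kT."""
    if len(peptide) != PEPTIDE_LENGTH:
        raise ValueError("peptide must have length 9")
    table = position_energy_table(hla, cmap, model)
    idx = [AA_INDEX[aa] for aa in peptide]
    return float(table[np.arange(PEPTIDE_LENGTH), idx].sum())


def stationary_distribution(
    hla: HlaSequence,
    cmap: ContactMap,
    model: InteractionModel,
    temperature: float = 1.0,
) -> np.ndarray:
    """Closed-form per-position Boltzmann distribution, shape (9, 20).

    Exact because the energy is additive over peptide positions:
    ``freq(a at p) ~ exp(-table[p, a] / T)``.
    """
    table = position_energy_table(hla, cmap, model)
    logw = -table / temperature
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def run_simulation(
    hla: HlaSequence,
    cmap: ContactMap,
    model: InteractionModel,
    config: SimulatorConfig,
) -> SimulationResult:
    """Run ``n_runs`` independent Metropolis chains over peptide sequences.

    Each chain starts from a uniformly random 9-mer and performs ``n_steps``
    single-position mutation proposals (position uniform over 1..9, new
    residue uniform over the other 19), accepted with probability
    ``min(1, exp(-dE / T))``. Final sequences are compiled into a PFM with
    the configured pseudocount. Per-chain random streams are derived from
    the master seed by run index, so results are deterministic per seed.
    """
    table = position_energy_table(hla, cmap, model)
    n_runs, n_steps = config.n_runs, config.n_steps
    children = np.random.SeedSequence(config.seed).spawn(n_runs)

    seqs = np.empty((n_runs, PEPTIDE_LENGTH), dtype=np.int64)
    pos = np.empty((n_steps, n_runs), dtype=np.int64)
    off = np.empty((n_steps, n_runs), dtype=np.int64)
    unif = np.empty((n_steps, n_runs), dtype=float)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        seqs[i] = rng.integers(0, N_AA, PEPTIDE_LENGTH)
        if n_steps:
            pos[:, i] = rng.integers(0, PEPTIDE_LENGTH, n_steps)
            off[:, i] = rng.integers(0, N_AA - 1, n_steps)
            unif[:, i] = rng.random(n_steps)

    rows = np.arange(n_runs)
    accepted = 0
    inv_t = 1.0 / config.temperature
    for t in range(n_steps):
        p = pos[t]
        cur = seqs[rows, p]
        new = (cur + 1 + off[t]) % N_AA
        d_e = table[p, new] - table[p, cur]
        # exponent clipped at 0: min(1, exp(-dE/T)) and u < 1 always
        acc = unif[t] < np.exp(np.minimum(-d_e * inv_t, 0.0))
        seqs[rows[acc], p[acc]] = new[acc]
        accepted += int(acc.sum())

    peptides = _decode_matrix(seqs)
    profile = compile_pfm(peptides, pseudocount=config.pseudocount, label=hla.allele)
    rate = None if n_steps == 0 else accepted / (n_runs * n_steps)
    return SimulationResult(
        final_peptides=peptides, profile=profile, acceptance_rate=rate
    )


def _decode_matrix(idx: np.ndarray) -> list[str]:
    chars = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return [bytes(chars[row]).decode("ascii") for row in idx.astype(np.intp)]


def mutate_hla(hla: HlaSequence, position: int, new_residue: str) -> HlaSequence:
    """Copy of ``hla`` with one residue replaced; label suffixed pos<n><old><new>."""
    old = hla.residue_at(position)
    if new_residue not in AA_INDEX:
        raise ValueError(f"{new_residue!r} is not an amino acid")
    if new_residue == old:
        raise ValueError(
            f"no-op mismatch: {hla.allele} already has {old} at position {position}"
        )
    residues = hla.residues[: position - 1] + new_residue + hla.residues[position:]
    return HlaSequence(
        allele=f"{hla.allele}_pos{position}{old}{new_residue}", residues=residues
    )


def mismatch_divergence(
    hla: HlaSequence,
    position: int,
    res_a: str,
    res_b: str,
    cmap: ContactMap,
    model: InteractionModel,
    config: SimulatorConfig,
) -> tuple[DivergenceResult, SimulationResult, SimulationResult]:
    """Simulate both residues of a mismatch on one template and compare.

    The template must already carry ``res_a`` or ``res_b`` at ``position``
    (template restriction); the other variant is created by a point
    mutation. Both simulations use independent streams derived from the
    config seed.
    """
    if res_a == res_b:
        raise ValueError(f"not a mismatch: {res_a}/{res_b}")
    current = hla.residue_at(position)
    if current not in (res_a, res_b):
        raise ValueError(
            f"template {hla.allele} has {current} at position {position}, "
            f"neither {res_a} nor {res_b}"
        )

    def variant(res: str) -> HlaSequence:
        return hla if res == current else mutate_hla(hla, position, res)

    tag = f"{position}:{res_a}:{res_b}"
    result_a = run_simulation(
        variant(res_a), cmap, model,
        replace(config, seed=derive_seed(config.seed, "mismatch", tag, "a")),
    )
    result_b = run_simulation(
        variant(res_b), cmap, model,
        replace(config, seed=derive_seed(config.seed, "mismatch", tag, "b")),
    )
    div = profile_divergence(result_a.profile, result_b.profile)
    return div, result_a, result_b


# ---------------------------------------------------------------------------
# TSV round-tripping for contact maps and interaction models
# ---------------------------------------------------------------------------

def write_contact_map(cmap: ContactMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# contact_map\npeptide_pos\thla_pos\tweight\n")
        for p, entries in enumerate(cmap.contacts, start=1):
            for h, w in entries:
                fh.write(f"{p}\t{h}\t{w:.10g}\n")


def read_contact_map(path) -> ContactMap:
    mapping: dict[int, list[tuple[int, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#") or ln.startswith("peptide_pos"):
                continue
            p_s, h_s, w_s = ln.split("\t")
            mapping.setdefault(int(p_s), []).append((int(h_s), float(w_s)))
    return ContactMap.from_dict(mapping)


def write_interaction_model(model: InteractionModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#\t" + "\t".join(ALPHABET) + "\n")
        for i, aa in enumerate(ALPHABET):
            fh.write(aa + "\t" + "\t".join(f"{v:.10g}" for v in model.energy[i]) + "\n")


def read_interaction_model(path) -> InteractionModel:
    energy = np.zeros((N_AA, N_AA))
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for ln in lines:
        if ln.startswith("#"):
            continue
        parts = ln.split("\t")
        aa = parts[0]
        if aa not in AA_INDEX or len(parts) != N_AA + 1:
            raise ValueError(f"malformed interaction model row: {ln[:40]!r}")
        energy[AA_INDEX[aa]] = [float(x) for x in parts[1:]]
    return InteractionModel(energy=energy)
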