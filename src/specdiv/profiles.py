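"""Position frequency matrices (PFMs) for 9-mer peptide binding and
divergence measures between them.

A binding profile is a 9x20 matrix of per-position amino-acid frequencies.
Two divergence measures between a pair of profiles are provided:

* per-position Jensen-Shannon divergence (base 2, each in [0, 1]) summed
  over the 9 positions, and
* one minus the Pearson correlation of additive log-frequency scores over
  a common random peptide panel ("affinity-correlation divergence").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import UndefinedResultError

#: The 20 canonical amino acids in fixed alphabetical order. All matrix
#: layouts (PFM columns, interaction-model axes) follow this order.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}
N_AA: int = 20
PEPTIDE_LENGTH: int = 9

# ascii byte -> alphabet index, -1 for anything else (fast string encoding)
_ASCII_LUT = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _ASCII_LUT[ord(_aa)] = _i


def encode_peptides(peptides: list[str]) -> np.ndarray:
    """Encode peptides as an (n, 9) int8 index array; validates symbols."""
    if len(peptides) == 0:
        raise ValueError("peptide list is empty")
    for pep in peptides:
        if len(pep) != PEPTIDE_LENGTH:
            raise ValueError(f"peptide {pep!r} does not have length {PEPTIDE_LENGTH}")
    raw = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    idx = _ASCII_LUT[raw].reshape(len(peptides), PEPTIDE_LENGTH)
    if (idx < 0).any():
        bad = int(np.argwhere((idx < 0).any(axis=1))[0, 0])
        raise ValueError(f"peptide {peptides[bad]!r} contains a non-alphabet symbol")
    return idx


def decode_peptides(idx: np.ndarray) -> list[str]:
    chars = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return [bytes(chars[row]).decode("ascii") for row in idx]


@dataclass(frozen=True)
class BindingProfile:
    """Per-position amino-acid frequencies of a 9-mer binding specificity."""

    label: str
    freqs: np.ndarray  # (9, 20), rows sum to 1

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (PEPTIDE_LENGTH, N_AA):
            raise ValueError(f"freqs must have shape (9, 20), got {f.shape}")
        if (f < 0).any():
            raise ValueError("frequencies must be nonnegative")
        sums = f.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0))) + 1
            raise ValueError(f"position {bad} frequencies sum to {sums[bad - 1]!r}, not 1")
        object.__setattr__(self, "freqs", f)

    @property
    def length(self) -> int:
        return PEPTIDE_LENGTH


@dataclass(frozen=True)
class DivergenceResult:
    """Per-position JSDs between two profiles and their sum."""

    per_position: np.ndarray  # (9,), each in [0, 1]
    total: float

    def __post_init__(self) -> None:
        pp = np.asarray(self.per_position, dtype=float)
        if pp.shape != (PEPTIDE_LENGTH,):
            raise ValueError("per_position must have 9 entries")
        if (pp < -1e-12).any() or (pp > 1 + 1e-12).any():
            raise ValueError("per-position divergences must lie in [0, 1]")
        if abs(float(pp.sum()) - self.total) > 1e-12:
            raise ValueError("total must equal the sum of per-position divergences")
        object.__setattr__(self, "per_position", pp)


@dataclass(frozen=True)
class DifferentialProfile:
    """Signed per-position frequency differences (A minus B)."""

    label_a: str
    label_b: str
    diffs: np.ndarray  # (9, 20), rows sum to 0
    column_height: np.ndarray  # (9,) per-position JSD used for display scaling


@dataclass(frozen=True)
class PeptidePanel:
    """A fixed panel of random 9-mers used to compare predicted affinities."""

    peptides: list[str]
    seed: int
    _encoded: np.ndarray = field(repr=False, compare=False, default=None)

    def encoded(self) -> np.ndarray:
        if self._encoded is None:
            object.__setattr__(self, "_encoded", encode_peptides(self.peptides))
        return self._encoded

    def __len__(self) -> int:
        return len(self.peptides)


def compile_pfm(
    peptides: list[str], pseudocount: float = 0.0, label: str = "pfm"
) -> BindingProfile:
    """Compile a list of 9-mers into a position frequency matrix.

    ``freqs[p][a] = (count(a at p) + pseudocount) / (N + 20 * pseudocount)``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    idx = encode_peptides(peptides)
    n = idx.shape[0]
    counts = np.zeros((PEPTIDE_LENGTH, N_AA), dtype=float)
    for p in range(PEPTIDE_LENGTH):
        counts[p] = np.bincount(idx[:, p], minlength=N_AA)
    freqs = (counts + pseudocount) / (n + N_AA * pseudocount)
    return BindingProfile(label=label, freqs=freqs)


def _entropy2(v: np.ndarray) -> float:
    nz = v[v > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd_column(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence between two probability vectors.

    Returns ``H(m) - (H(p) + H(q)) / 2`` with ``m = (p + q) / 2`` and
    entropies in bits, so the result lies in [0, 1]. ``0 * log 0`` is 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any():
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} sums to {v.sum()!r}, not 1")
    m = 0.5 * (p + q)
    d = _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))
    # numerical noise can push the value a hair outside [0, 1]
    return min(1.0, max(0.0, d))


def profile_divergence(a: BindingProfile, b: BindingProfile) -> DivergenceResult:
    """Per-position JSD between two profiles plus their sum over 9 positions."""
    if a.freqs.shape != b.freqs.shape:
        raise ValueError("profiles have mismatched shapes")
    per = np.array(
        [jsd_column(a.freqs[p], b.freqs[p]) for p in range(PEPTIDE_LENGTH)]
    )
    return DivergenceResult(per_position=per, total=float(per.sum()))


def differential_profile(a: BindingProfile, b: BindingProfile) -> DifferentialProfile:
    """Signed frequency differences (a - b) with per-position JSD heights."""
    if a.freqs.shape != b.freqs.shape:
        raise ValueError("profiles have mismatched shapes")
    div = profile_divergence(a, b)
    return DifferentialProfile(
        label_a=a.label,
        label_b=b.label,
        diffs=a.freqs - b.freqs,
        column_height=div.per_position,
    )


def score_peptide(profile: BindingProfile, peptide: str, alpha: float = 0.001) -> float:
    """Additive log2 pseudo-affinity of a 9-mer under a profile.

    Sum over positions of ``log2((f[p][aa] + alpha) / (1 + 20 * alpha))``;
    higher means better predicted binding.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    idx = encode_peptides([peptide])[0]
    f = profile.freqs[np.arange(PEPTIDE_LENGTH), idx]
    if alpha == 0 and (f == 0).any():
        raise ValueError(
            "peptide hits a zero frequency with alpha=0; use a nonzero alpha"
        )
    return float(np.log2((f + alpha) / (1 + N_AA * alpha)).sum())


def score_panel(
    profile: BindingProfile, panel: PeptidePanel, alpha: float = 0.001
) -> np.ndarray:
    """Vectorized :func:`score_peptide` over a panel; returns (n,) scores."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    idx = panel.encoded()
    f = profile.freqs[np.arange(PEPTIDE_LENGTH)[None, :], idx]
    if alpha == 0 and (f == 0).any():
        raise ValueError(
            "panel hits a zero frequency with alpha=0; use a nonzero alpha"
        )
    return np.log2((f + alpha) / (1 + N_AA * alpha)).sum(axis=1)


def make_random_panel(n: int, seed: int) -> PeptidePanel:
    """Draw ``n`` 9-mers with i.i.d. uniform residues; deterministic per seed."""
    if n < 1:
        raise ValueError("panel size must be at least 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, N_AA, size=(n, PEPTIDE_LENGTH), dtype=np.int8)
    return PeptidePanel(peptides=decode_peptides(idx), seed=seed)


def affinity_correlation_divergence(
    a: BindingProfile,
    b: BindingProfile,
    panel: PeptidePanel,
    alpha: float = 0.001,
) -> float:
    """Divergence as 1 minus the Pearson correlation of panel scores.

    Raises :class:`UndefinedResultError` when either score vector has zero
    variance (the correlation, hence the divergence, is undefined).
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    sa = score_panel(a, panel, alpha)
    sb = score_panel(b, panel, alpha)
    # summation-order noise can leave a ~1e-15 std on constant score vectors
    tol_a = 1e-12 * (1 + abs(float(sa.mean())))
    tol_b = 1e-12 * (1 + abs(float(sb.mean())))
    if sa.std() <= tol_a or sb.std() <= tol_b:
        raise UndefinedResultError(
            "score variance is zero for at least one profile; "
            "affinity-correlation divergence undefined"
        )
    if np.array_equal(sa, sb):
        return 0.0
    r = float(np.corrcoef(sa, sb)[0, 1])
    return 1.0 - r


# ---------------------------------------------------------------------------
# PFM TSV round-tripping
# ---------------------------------------------------------------------------

_PFM_HEADER_PREFIX = "# pfm "


def write_pfm(profile: BindingProfile, path) -> None:
    """Write a profile as TSV: header line then 9 rows of 20 frequencies."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pfm {profile.label} length=9 alphabet={ALPHABET}\n")
        for p in range(PEPTIDE_LENGTH):
            vals = "\t".join(f"{v:.10g}" for v in profile.freqs[p])
            fh.write(f"{p + 1}\t{vals}\n")


def read_pfm(path) -> BindingProfile:
    """Read a profile written by :func:`write_pfm`; validates normalization."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(_PFM_HEADER_PREFIX):
        raise ValueError(f"{path}: malformed PFM header")
    header = lines[0][len(_PFM_HEADER_PREFIX):].split()
    if len(header) < 3 or header[-2] != "length=9" or header[-1] != f"alphabet={ALPHABET}":
        raise ValueError(f"{path}: malformed PFM header fields")
    label = " ".join(header[:-2])
    rows = lines[1:]
    if len(rows) != PEPTIDE_LENGTH:
        raise ValueError(f"{path}: expected 9 data rows, found {len(rows)}")
    freqs = np.zeros((PEPTIDE_LENGTH, N_AA))
    for i, row in enumerate(rows):
        parts = row.split("\t")
        if len(parts) != N_AA + 1:
            raise ValueError(f"{path}: row {i + 1} has {len(parts) - 1} frequencies")
        pos = int(parts[0])
        if pos != i + 1:
            raise ValueError(f"{path}: row {i + 1} labeled position {pos}")
        vals = np.array([float(x) for x in parts[1:]])
        if (vals < 0).any():
            raise ValueError(f"{path}: negative frequency at position {pos}")
        s = vals.sum()
        if abs(s - 1.0) > 1e-4:
            raise ValueError(f"{path}: position {pos} frequencies sum to {s}, not 1")
        freqs[i] = vals / s
    return BindingProfile(label=label, freqs=freqs)


def uniform_profile(label: str = "uniform") -> BindingProfile:
    """The flat profile: every residue frequency 0.05 at every position."""
    return BindingProfile(label=label, freqs=np.full((PEPTIDE_LENGTH, N_AA), 1 / N_AA))
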