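import numpy as np
import pytest

from specdiv import (
    HlaSequence,
    SimulatorConfig,
    TransplantPair,
    build_contact_map,
    default_interaction_model,
    generate_toy_structure,
)
from specdiv.synth import TOY_HLA_CHAIN, TOY_PEPTIDE_CHAIN


@pytest.fixture(scope="session")
def toy_pdb() -> str:
    return generate_toy_structure(seed=0)


@pytest.fixture(scope="session")
def toy_cmap(toy_pdb):
    return build_contact_map(toy_pdb, TOY_HLA_CHAIN, TOY_PEPTIDE_CHAIN, cutoff=4.5)


@pytest.fixture(scope="session")
def interaction_model():
    return default_interaction_model()


@pytest.fixture(scope="session")
def hla30() -> HlaSequence:
    # 30 residues, long enough for the toy contact map (max HLA position 11)
    return HlaSequence(allele="T*01", residues="ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")


@pytest.fixture
def fast_config() -> SimulatorConfig:
    return SimulatorConfig(n_runs=400, n_steps=120, seed=7, pseudocount=0.5)


def make_pair(pair_id, patient_seq, donor_seq, death, severity="low",
              patient_allele=None, donor_allele=None):
    """Small helper for hand-built cohorts; alleles default to the sequences."""
    return TransplantPair(
        pair_id=pair_id,
        patient_allele=patient_allele or f"AL*{patient_seq}",
        donor_allele=donor_allele or f"AL*{donor_seq}",
        patient_seq=patient_seq,
        donor_seq=donor_seq,
        death=death,
        severity=severity,
    )


@pytest.fixture
def hand_cohort():
    """10 pairs: mismatch (5, A/C) carried by 4 pairs with oriented tallies
    (2 pairs, 1 death) / (2 pairs, 2 deaths); 6 complement pairs, 2 deaths.

    Symmetrized rate 1.0, complement rate 1/3, relative risk 3.0.
    """
    base = "AAAAAAAAAA"
    with_ac = base[:4] + "C" + base[5:]  # C at position 5
    other = base[:6] + "D" + base[7:]  # complement pairs differ at position 7
    pairs = [
        make_pair("c1", base, with_ac, death=1),  # orientation A->C
        make_pair("c2", base, with_ac, death=0),
        make_pair("c3", with_ac, base, death=1),  # orientation C->A
        make_pair("c4", with_ac, base, death=1),
    ]
    for i in range(6):
        pairs.append(make_pair(f"o{i}", base, other, death=1 if i < 2 else 0))
    return pairs


def random_cohort(rng, n_pairs=None, n_positions=8, n_res=3):
    """Randomized small cohort over a tiny alphabet, for brute-force checks."""
    n_pairs = n_pairs or int(rng.integers(3, 31))
    residues = "ACD"[:n_res]
    pairs = []
    attempts = 0
    while len(pairs) < n_pairs and attempts < 50 * n_pairs:
        attempts += 1
        pseq = "".join(rng.choice(list(residues), n_positions))
        dseq = "".join(rng.choice(list(residues), n_positions))
        if pseq == dseq:
            continue
        # a few shared allele labels so subsampling groups are nontrivial
        pairs.append(
            make_pair(
                f"r{len(pairs)}",
                pseq,
                dseq,
                death=int(rng.integers(0, 2)),
                severity=("low", "intermediate", "high")[int(rng.integers(0, 3))],
                patient_allele=f"AL*{int(rng.integers(0, 4)):02d}",
                donor_allele=f"AL*{int(rng.integers(4, 8)):02d}",
            )
        )
    return pairs
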