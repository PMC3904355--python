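"""Independent reference implementations used as test oracles.

Deliberately naive: direct formulas, explicit loops and brute-force
enumeration, sharing no code paths with the package internals.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


def textbook_jsd(p, q) -> float:
    """H(m) - (H(p) + H(q)) / 2 evaluated term by term in base 2."""

    def h(v):
        return -sum(x * math.log2(x) for x in v if x > 0)

    m = [(a + b) / 2 for a, b in zip(p, q)]
    return h(m) - (h(p) + h(q)) / 2


def counting_pfm(peptides, pseudocount=0.0):
    """Frequency matrix by explicit counting (9 x 20 nested lists)."""
    n = len(peptides)
    out = []
    for pos in range(9):
        col = []
        for aa in AA:
            c = sum(1 for pep in peptides if pep[pos] == aa)
            col.append((c + pseudocount) / (n + 20 * pseudocount))
        out.append(col)
    return out


def hand_pearson(x, y):
    """Pearson r and its two-sided t-based p-value from first principles."""
    from scipy.stats import t as t_dist

    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) >= 1:
        return r, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return r, 2 * t_dist.sf(abs(t), n - 2)


def brute_force_risk(cohort, threshold, rate_mode="raw"):
    """Enumerate mismatches pair by pair and compute raw risk statistics.

    Returns {(position, res_a, res_b): dict} for mismatches whose both
    oriented counts reach the threshold. Rates are raw (no subsampling);
    use cap >= all group sizes in the pipeline to compare.
    """
    oriented = defaultdict(list)  # (pos, pat, don) -> [death, ...]
    carriers = defaultdict(set)  # unoriented key -> pair ids
    carrier_deaths = defaultdict(int)
    for pair in cohort:
        seen = set()
        for i, (p, d) in enumerate(zip(pair.patient_seq, pair.donor_seq)):
            if p == d:
                continue
            pos = i + 1
            oriented[(pos, p, d)].append(pair.death)
            key = (pos, min(p, d), max(p, d))
            if key not in seen:
                carriers[key].add(pair.pair_id)
                carrier_deaths[key] += pair.death
                seen.add(key)
    total_deaths = sum(p.death for p in cohort)
    n = len(cohort)
    out = {}
    for key in carriers:
        pos, ra, rb = key
        o1 = oriented.get((pos, ra, rb), [])
        o2 = oriented.get((pos, rb, ra), [])
        if min(len(o1), len(o2)) < threshold:
            continue
        rates = []
        for o in (o1, o2):
            if o:
                rates.append(sum(o) / len(o))
        rate_sym = max(rates)
        n_comp = n - len(carriers[key])
        d_comp = total_deaths - carrier_deaths[key]
        rate_comp = d_comp / n_comp if n_comp else None
        rr = None
        if rate_comp:
            rr = rate_sym / rate_comp
        out[key] = {
            "count_or1": len(o1),
            "count_or2": len(o2),
            "rate_or1": sum(o1) / len(o1) if o1 else None,
            "rate_or2": sum(o2) / len(o2) if o2 else None,
            "rate_symmetrized": rate_sym,
            "rate_complement": rate_comp,
            "relative_risk": rr,
        }
    return out


def boltzmann_by_hand(hla_residues, contacts, e_fn, temperature=1.0):
    """Per-position stationary distribution by explicit summation.

    ``contacts`` is {peptide_pos (1-based): [(hla_pos, weight), ...]};
    ``e_fn(a, b)`` the pair energy.
    """
    probs = []
    for p in range(1, 10):
        ws = []
        for aa in AA:
            energy = 0.0
            for h, w in contacts.get(p, []):
                energy += w * e_fn(aa, hla_residues[h - 1])
            ws.append(math.exp(-energy / temperature))
        z = sum(ws)
        probs.append([w / z for w in ws])
    return np.array(probs)


def random_profile(rng, label="rand", concentration=1.0):
    """A valid random BindingProfile via per-position Dirichlet draws."""
    from specdiv import BindingProfile

    freqs = rng.dirichlet(np.full(20, concentration), size=9)
    return BindingProfile(label=label, freqs=freqs)
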