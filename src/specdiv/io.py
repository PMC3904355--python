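"""Plain-text readers and writers for the pipeline's table formats.

All tables are UTF-8 TSV with '#'-prefixed metadata lines before the
column header. Sequences travel as FASTA keyed by allele label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cohort import SEVERITIES, TransplantPair, UnorientedMismatch
from .mc import HlaSequence
from .profiles import DivergenceResult, PEPTIDE_LENGTH

_FLOAT_FMT = "%.10g"


def write_fasta(sequences: list[HlaSequence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sequences:
            fh.write(f">{s.allele}\n{s.residues}\n")


def read_fasta(path) -> dict[str, HlaSequence]:
    out: dict[str, HlaSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = HlaSequence(allele=rec.id, residues=str(rec.seq).upper())
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def _write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- cohort ------------------------------------------------------------------

_COHORT_COLS = ["pair_id", "patient_allele", "donor_allele", "death", "severity"]


def write_cohort(cohort: list[TransplantPair], path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "patient_allele": p.patient_allele,
                "donor_allele": p.donor_allele,
                "death": p.death,
                "severity": p.severity,
            }
            for p in cohort
        ],
        columns=_COHORT_COLS,
    )
    _write_tsv(df, path, meta)


def read_cohort(cohort_path, fasta_path) -> list[TransplantPair]:
    """Load a cohort TSV, resolving allele sequences from a FASTA file.

    Unknown alleles or severity labels raise at load time.
    """
    seqs = read_fasta(fasta_path)
    df = _read_tsv(cohort_path, dtype={"pair_id": str})
    missing = set(_COHORT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{cohort_path}: missing columns {sorted(missing)}")
    cohort = []
    for row in df.itertuples(index=False):
        if row.severity not in SEVERITIES:
            raise ValueError(
                f"{cohort_path}: pair {row.pair_id}: unknown severity {row.severity!r}"
            )
        for allele in (row.patient_allele, row.donor_allele):
            if allele not in seqs:
                raise ValueError(
                    f"{cohort_path}: pair {row.pair_id}: allele {allele!r} "
                    f"not in {fasta_path}"
                )
        cohort.append(
            TransplantPair(
                pair_id=str(row.pair_id),
                patient_allele=row.patient_allele,
                donor_allele=row.donor_allele,
                patient_seq=seqs[row.patient_allele].residues,
                donor_seq=seqs[row.donor_allele].residues,
                death=int(row.death),
                severity=row.severity,
            )
        )
    return cohort


# -- ground truth ------------------------------------------------------------

def write_ground_truth(delta: dict[UnorientedMismatch, float], path,
                       meta: dict | None = None) -> None:
    rows = [
        {"position": um.position, "res_a": um.res_a, "res_b": um.res_b, "delta": d}
        for um, d in sorted(delta.items())
    ]
    _write_tsv(pd.DataFrame(rows, columns=["position", "res_a", "res_b", "delta"]),
               path, meta)


def read_ground_truth(path) -> dict[UnorientedMismatch, float]:
    df = _read_tsv(path)
    return {
        UnorientedMismatch.of(int(r.position), r.res_a, r.res_b): float(r.delta)
        for r in df.itertuples(index=False)
    }


# -- divergence report -------------------------------------------------------

_DIV_COLS = (
    ["position", "res_a", "res_b", "label_a", "label_b"]
    + [f"d_pos{i}" for i in range(1, PEPTIDE_LENGTH + 1)]
    + ["total", "corr_divergence"]
)


def divergence_row(
    mismatch: UnorientedMismatch,
    label_a: str,
    label_b: str,
    div: DivergenceResult,
    corr_divergence: float | None = None,
) -> dict:
    row = {
        "position": mismatch.position,
        "res_a": mismatch.res_a,
        "res_b": mismatch.res_b,
        "label_a": label_a,
        "label_b": label_b,
        "total": div.total,
        "corr_divergence": np.nan if corr_divergence is None else corr_divergence,
    }
    for i in range(PEPTIDE_LENGTH):
        row[f"d_pos{i + 1}"] = div.per_position[i]
    return row


def write_divergence_table(rows: list[dict], path, meta: dict | None = None) -> None:
    df = pd.DataFrame(rows, columns=_DIV_COLS)
    df = df.rename(columns={"total": "divergence_total"})
    _write_tsv(df, path, meta)


def read_divergence_table(path) -> pd.DataFrame:
    return _read_tsv(path)


# -- risk / scatter / summary ------------------------------------------------

def write_risk_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(df, path, meta)


def read_risk_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_scatter(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(df, path, meta)


def write_summary(result, path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "n": result.n,
                "pearson_r": result.pearson_r,
                "pearson_p": result.pearson_p,
                "spearman_r": result.spearman_r,
                "spearman_p": result.spearman_p,
                "n_dropped": result.n_dropped,
            }
        ]
    )
    _write_tsv(df, path, meta)
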