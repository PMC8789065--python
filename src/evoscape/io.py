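"""FASTA and tabular I/O helpers (Biopython-backed)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import PROTEIN, Alphabet

__all__ = ["read_msa", "write_msa", "read_dna_fasta", "write_mutant_scan"]


def read_msa(path, alphabet: Alphabet = PROTEIN):
    """Read an aligned FASTA; returns (ids, (M, L) int8 array)."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise ValueError(f"{path}: no sequences")
    return ids, alphabet.encode_msa(seqs)


def write_msa(path, msa: np.ndarray, ids=None, alphabet: Alphabet = PROTEIN,
              descriptions=None) -> None:
    """Write an (M, L) index array as aligned FASTA."""
    msa = np.asarray(msa)
    records = []
    for m, row in enumerate(msa):
        rid = ids[m] if ids is not None else f"seq_{m}"
        desc = descriptions[m] if descriptions is not None else ""
        records.append(SeqRecord(Seq(alphabet.decode(row)), id=rid, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_dna_fasta(path) -> str:
    """Read the first record of a nucleotide FASTA as an upper-case string."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return str(rec.seq).upper()
    raise ValueError(f"{path}: no sequences")


def write_mutant_scan(path, scan: np.ndarray, wildtype, alphabet: Alphabet = PROTEIN) -> None:
    """Write a mutant scan as TSV (site, wildtype_aa, mutant_aa, deltaE)."""
    wt = alphabet.encode(wildtype) if isinstance(wildtype, str) else np.asarray(wildtype)
    targets = [s for s in alphabet.symbols if s != alphabet.gap]
    rows = []
    for i in range(scan.shape[0]):
        for k, b in enumerate(targets):
            rows.append((i, alphabet.symbols[wt[i]], b, scan[i, k]))
    pd.DataFrame(rows, columns=["site", "wildtype_aa", "mutant_aa", "deltaE"]).to_csv(
        path, sep="\t", index=False)
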