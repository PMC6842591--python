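"""Readers and writers for standard repertoire formats.

AIRR Rearrangement TSV (sequence_id, clone_id, sequence_alignment,
germline_alignment) is the primary exchange format; region masks are
two-column TSVs (0-based codon_index, label FWR/CDR/IGNORED), with CDR3
exclusion expressed as IGNORED labels.
"""

from __future__ import annotations

import logging

import pandas as pd

from .codon_space import IGNORED, RegionMask
from .phylo_likelihood import LineageData, Repertoire

logger = logging.getLogger(__name__)

AIRR_REQUIRED = ("sequence_id", "clone_id", "sequence_alignment", "germline_alignment")


def _clean(seq: str) -> str:
    """IMGT '.' gap characters become '-' gaps; case is normalized."""
    return str(seq).upper().replace(".", "-")


def read_airr(path, mask: RegionMask | None = None) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a Repertoire skeleton (no trees).

    Rows are grouped by ``clone_id``; alignment lengths must agree within a
    clone, and sequence ids must be unique.  Without an explicit mask,
    every codon site is labelled FWR.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"AIRR file {path} is missing required columns: {missing}")
    dupes = df["sequence_id"][df["sequence_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate sequence_id values: {sorted(set(dupes))[:5]}")

    lineages = []
    for clone_id, grp in df.groupby("clone_id", sort=False):
        seqs = {row.sequence_id: _clean(row.sequence_alignment)
                for row in grp.itertuples()}
        germs = {_clean(g) for g in grp["germline_alignment"]}
        if len(germs) > 1:
            logger.warning("clone %s: multiple germline_alignment values; using the first",
                           clone_id)
        germline = _clean(grp["germline_alignment"].iloc[0])
        lengths = {len(s) for s in seqs.values()} | {len(germline)}
        if len(lengths) != 1:
            bad = next(sid for sid, s in seqs.items() if len(s) != len(germline))
            raise ValueError(
                f"clone {clone_id}: alignment length mismatch (e.g. sequence {bad})")
        m = mask if mask is not None else RegionMask.uniform(len(germline) // 3)
        lineages.append(LineageData(name=str(clone_id), sequences=seqs,
                                    germline=germline, mask=m))
    return Repertoire(lineages=lineages)


def write_airr(rep: Repertoire, path) -> None:
    rows = [
        {"sequence_id": sid, "clone_id": lin.name,
         "sequence_alignment": seq, "germline_alignment": lin.germline}
        for lin in rep.lineages for sid, seq in lin.sequences.items()
    ]
    pd.DataFrame(rows, columns=list(AIRR_REQUIRED)).to_csv(path, sep="\t", index=False)


def read_mask_tsv(path) -> RegionMask:
    df = pd.read_csv(path, sep="\t", header=None, names=["codon_index", "label"],
                     comment="#", dtype={0: int, 1: str})
    n = df["codon_index"].max() + 1
    if sorted(df["codon_index"]) != list(range(n)):
        raise ValueError(f"mask file {path} must cover codon indices 0..{n - 1} exactly once")
    labels = [IGNORED] * n
    for row in df.itertuples():
        labels[row.codon_index] = row.label.strip().upper()
    return RegionMask(tuple(labels))


def write_mask_tsv(mask: RegionMask, path) -> None:
    with open(path, "w") as fh:
        for i, label in enumerate(mask.labels):
            fh.write(f"{i}\t{label}\n")
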