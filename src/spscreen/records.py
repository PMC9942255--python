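"""Domain model for tripartite signal peptides.

A Sec-type signal peptide (SP) is modelled as four juxtaposed segments of the
amino-acid sequence: a positively charged N-region, a hydrophobic H-region, a
polar C-region ending in the signal-peptidase (SPase I) recognition site, and
the first three residues of the mature protein after the cleavage site (the
"Ac" region).  Coordinates are 0-based half-open: ``N = [0, n_end)``,
``H = [n_end, h_end)``, ``C = [h_end, c_end)``, ``Ac = [c_end, c_end + 3)``.
The SPase cleavage site sits between ``c_end - 1`` and ``c_end``, so the
biological -3/-2/-1 positions are ``aa_seq[c_end - 3 : c_end]``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
REGIONS = ("N", "H", "C", "Ac", "SP")


@dataclass(frozen=True)
class SPRecord:
    """One signal peptide plus the start of its mature protein.

    ``aa_seq`` holds the SP residues followed by at least three
    mature-protein residues; ``nt_seq``, when present, is the coding
    sequence of ``aa_seq`` (3x length, in-frame).
    """

    id: str
    aa_seq: str
    n_end: int
    h_end: int
    c_end: int
    nt_seq: str | None = None

    def with_nt(self, nt_seq: str) -> "SPRecord":
        return replace(self, nt_seq=nt_seq)


def validate_record(rec: SPRecord, codon_table: int | str = 1) -> list[str]:
    """Return the list of invariant violations for ``rec`` (empty if valid)."""
    violations: list[str] = []
    n = len(rec.aa_seq)
    if not rec.aa_seq:
        return ["empty sequence"]
    if rec.aa_seq[0] != "M":
        violations.append("missing initiator Met")
    bad = set(rec.aa_seq) - AA_ALPHABET
    if bad:
        violations.append(f"non-standard residues: {sorted(bad)}")
    if not 0 < rec.n_end:
        violations.append("empty N-region")
    if not rec.n_end < rec.h_end:
        violations.append("empty H-region")
    if not rec.h_end < rec.c_end:
        violations.append("empty C-region")
    if not rec.c_end <= n - 3:
        violations.append("fewer than 3 residues after the cleavage site")
    if rec.nt_seq is not None:
        if len(rec.nt_seq) != 3 * n:
            violations.append("nt_seq length is not 3x aa_seq length")
        else:
            translated = str(Seq(rec.nt_seq).translate(table=codon_table))
            if translated != rec.aa_seq:
                violations.append("nt_seq does not translate to aa_seq")
    return violations


def extract_region(rec: SPRecord, region: str) -> str:
    """Slice one region out of ``rec``; ``"SP"`` is the N+H+C concatenation."""
    if region == "N":
        return rec.aa_seq[: rec.n_end]
    if region == "H":
        return rec.aa_seq[rec.n_end : rec.h_end]
    if region == "C":
        return rec.aa_seq[rec.h_end : rec.c_end]
    if region == "Ac":
        return rec.aa_seq[rec.c_end : rec.c_end + 3]
    if region == "SP":
        return rec.aa_seq[: rec.c_end]
    raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


def cleavage_context(rec: SPRecord) -> tuple[str, str, str]:
    """Residues at the -3, -2 and -1 positions of the SPase cleavage site."""
    if rec.c_end - rec.h_end < 3:
        raise ValueError("C-region shorter than 3 residues has no -3/-2/-1 context")
    return (rec.aa_seq[rec.c_end - 3], rec.aa_seq[rec.c_end - 2], rec.aa_seq[rec.c_end - 1])


# ---------------------------------------------------------------------------
# IO: FASTA (aa/nt) plus a sidecar region table (id, n_end, h_end, c_end)
# ---------------------------------------------------------------------------

def read_records(
    aa_fasta: str | Path,
    regions_tsv: str | Path,
    nt_fasta: str | Path | None = None,
) -> list[SPRecord]:
    """Load SPRecords from an amino-acid FASTA and its region sidecar table."""
    aa = {r.id: str(r.seq) for r in SeqIO.parse(str(aa_fasta), "fasta")}
    nt: dict[str, str] = {}
    if nt_fasta is not None:
        nt = {r.id: str(r.seq) for r in SeqIO.parse(str(nt_fasta), "fasta")}
    bounds = pd.read_csv(regions_tsv, sep="\t", dtype={"id": str}).set_index("id")
    records = []
    for sp_id, row in bounds.iterrows():
        if sp_id not in aa:
            raise KeyError(f"region table id {sp_id!r} missing from {aa_fasta}")
        records.append(
            SPRecord(
                id=str(sp_id),
                aa_seq=aa[sp_id],
                n_end=int(row["n_end"]),
                h_end=int(row["h_end"]),
                c_end=int(row["c_end"]),
                nt_seq=nt.get(sp_id),
            )
        )
    return records


def write_records(
    records: Sequence[SPRecord],
    aa_fasta: str | Path,
    regions_tsv: str | Path,
    nt_fasta: str | Path | None = None,
) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.aa_seq), id=r.id, description="") for r in records),
        str(aa_fasta),
        "fasta",
    )
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "n_end": [r.n_end for r in records],
            "h_end": [r.h_end for r in records],
            "c_end": [r.c_end for r in records],
        }
    ).to_csv(regions_tsv, sep="\t", index=False)
    if nt_fasta is not None:
        with_nt = [r for r in records if r.nt_seq is not None]
        SeqIO.write(
            (SeqRecord(Seq(r.nt_seq), id=r.id, description="") for r in with_nt),
            str(nt_fasta),
            "fasta",
        )


def validate_all(records: Iterable[SPRecord]) -> dict[str, list[str]]:
    """Map record id -> violations, for records that fail validation."""
    out = {}
    for rec in records:
        v = validate_record(rec)
        if v:
            out[rec.id] = v
    return out
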