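"""Physicochemical descriptors for peptide and coding sequences.

Amino-acid level: scale aggregates (GRAVY, Boman index, flexibility, Ez),
residue frequencies, integer net charge, Henderson-Hasselbalch isoelectric
point, helix-breaker turn indicator and the 40 cleavage-site dummies.
Nucleotide level: codon adaptation index from RSCU weights and an RNA
secondary-structure folding proxy (Nussinov-style base-pair maximization;
more pairing -> more negative value, mirroring a folding energy).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from . import scales

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


HELIX_BREAKERS = frozenset("GPSND")
POSITIVE_RESIDUES = frozenset("RK")
NEGATIVE_RESIDUES = frozenset("DE")
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def compute_scale_feature(seq: str, scale: dict[str, float], aggregator: str = "mean") -> float:
    """Mean (default) or sum of per-residue scale values over ``seq``."""
    if not seq:
        raise ValueError("cannot aggregate a scale over an empty sequence")
    try:
        values = [scale[aa] for aa in seq]
    except KeyError as exc:
        raise KeyError(f"residue {exc.args[0]!r} absent from scale table") from exc
    total = math.fsum(values)
    if aggregator == "sum":
        return total
    if aggregator == "mean":
        return total / len(values)
    raise ValueError(f"unknown aggregator {aggregator!r}")


def compute_aa_frequency(seq: str, residue: str) -> float:
    if not seq:
        raise ValueError("cannot compute residue frequency of an empty sequence")
    return seq.count(residue) / len(seq)


def compute_net_charge(seq: str) -> float:
    """Integer side-chain counting: (#R + #K) - (#D + #E); His counts 0."""
    if not seq:
        raise ValueError("cannot compute net charge of an empty sequence")
    pos = sum(seq.count(aa) for aa in POSITIVE_RESIDUES)
    neg = sum(seq.count(aa) for aa in NEGATIVE_RESIDUES)
    return float(pos - neg)


def charge_at_ph(seq: str, ph: float, pka: dict[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge at ``ph`` including both termini."""
    if not seq:
        raise ValueError("empty sequence")
    pka = pka or scales.pka_emboss()
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa, count in ((aa, seq.count(aa)) for aa in "KRH"):
        if count and aa in pka:
            charge += count / (1.0 + 10 ** (ph - pka[aa]))
    for aa in "DECY":
        count = seq.count(aa)
        if count and aa in pka:
            charge -= count / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def compute_isoelectric_point(
    seq: str, pka: dict[str, float] | None = None, tol: float = 1e-3
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    if not seq:
        raise ValueError("cannot compute pI of an empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if charge_at_ph(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_turn_indicator(first_c_residue: str, breakers: frozenset[str] = HELIX_BREAKERS) -> int:
    """1 iff the residue that ends the H-helix (first C residue) breaks helices."""
    return int(first_c_residue in breakers)


def compute_cleavage_dummies(minus3: str, minus1: str) -> dict[str, int]:
    """One-hot encode the -3 and -1 cleavage-site residues (40 dummies)."""
    dummies = {f"-3_{aa}": 0 for aa in AMINO_ACIDS}
    dummies.update({f"-1_{aa}": 0 for aa in AMINO_ACIDS})
    dummies[f"-3_{minus3}"] = 1
    dummies[f"-1_{minus1}"] = 1
    return dummies


# ---------------------------------------------------------------------------
# Codon-level descriptors
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _synonymous_families(table_id: int = 1) -> dict[str, tuple[str, ...]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    families: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        families.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(codons)) for aa, codons in families.items()}


def rscu_weights(
    usage: dict[str, float] | None = None, table_id: int = 1
) -> dict[str, float]:
    """CAI weights w(codon) = RSCU / max family RSCU from a usage table."""
    usage = usage or scales.codon_usage()
    weights: dict[str, float] = {}
    for aa, codons in _synonymous_families(table_id).items():
        freqs = [usage.get(c, 0.0) for c in codons]
        top = max(freqs)
        if top <= 0:
            raise ValueError(f"codon usage table has no counts for {aa}")
        for codon, f in zip(codons, freqs):
            weights[codon] = f / top
    return weights


def most_frequent_codons(
    usage: dict[str, float] | None = None, table_id: int = 1
) -> dict[str, str]:
    """Per amino acid, the most used codon (ties: lexicographically smallest)."""
    usage = usage or scales.codon_usage()
    best: dict[str, str] = {}
    for aa, codons in _synonymous_families(table_id).items():
        best[aa] = max(codons, key=lambda c: (usage.get(c, 0.0), [-ord(x) for x in c]))
    return best


_SINGLE_CODON_AAS = frozenset("MW")


def compute_cai(
    nt_seq: str,
    weights: dict[str, float] | None = None,
    table_id: int = 1,
) -> float:
    """Codon adaptation index: geometric mean of RSCU weights.

    Met/Trp codons (degenerate families of one) and stop codons are excluded
    from the geometric mean.
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError("nucleotide sequence length must be a multiple of 3")
    weights = weights if weights is not None else rscu_weights(table_id=table_id)
    table = CodonTable.unambiguous_dna_by_id[table_id]
    log_sum, n = 0.0, 0
    seq = nt_seq.upper().replace("U", "T")
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in table.stop_codons:
            continue
        aa = table.forward_table.get(codon)
        if aa is None:
            raise KeyError(f"codon {codon!r} absent from the codon table")
        if aa in _SINGLE_CODON_AAS:
            continue
        w = weights[codon]
        if w <= 0:
            raise ValueError(f"codon {codon} has non-positive weight")
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise ValueError("no informative codons for CAI")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# RNA folding proxy: Nussinov base-pair maximization (minimum loop 3)
# ---------------------------------------------------------------------------

_NT_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


@njit(cache=True)
def _nussinov_max_pairs(codes: np.ndarray, min_loop: int) -> int:  # pragma: no cover
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                a, b = codes[i], codes[k]
                paired = (
                    (a == 0 and b == 3)
                    or (a == 3 and b == 0)
                    or (a == 2 and b == 1)
                    or (a == 1 and b == 2)
                    or (a == 2 and b == 3)
                    or (a == 3 and b == 2)
                )
                if paired:
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    rest = dp[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp[0, n - 1] if n > 1 else 0


def compute_rna_mfe(nt_seq: str, min_loop: int = 3) -> float:
    """Negated maximal number of nested WC/GU pairs (default folding proxy).

    A pluggable thermodynamic backend can replace this at the encoder level;
    here "more folding" maps to a more negative value, mirroring an energy.
    """
    if not nt_seq:
        raise ValueError("empty nucleotide sequence")
    try:
        codes = np.array([_NT_CODE[c] for c in nt_seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGU/T character {exc.args[0]!r} in sequence") from exc
    if len(codes) <= min_loop + 1:
        return 0.0
    return -float(_nussinov_max_pairs(codes, min_loop))
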