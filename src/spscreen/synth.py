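"""Synthetic sort-seq screen: reference SPs, designed single-edit libraries
and simulated bin counts with known ground truth.

The generator emulates the structure of a secretion screen without any real
data: reference SPs have a positively charged N-region, a hydrophobic
H-region and an AxA-biased cleavage site; the designed library edits one
physicochemical feature at a time; and read counts are drawn per SP from a
multinomial over 10 bins whose probabilities are a discretized Gaussian
centered on a known true WA.  Per-bin NLR occupancy modulates the read
probabilities, so occupancy normalization is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import descriptors
from .features.scales import kyte_doolittle as _kd_loader
from .records import SPRecord, extract_region
from .scoring import BinCountTable

_KD = _kd_loader()

# -- reference-set composition (residue pools per region) -------------------
_N_BODY = (("K", 0.40), ("R", 0.22), ("S", 0.12), ("N", 0.08), ("T", 0.06), ("A", 0.08), ("Q", 0.04))
_H_CORE = (("L", 0.34), ("A", 0.18), ("I", 0.14), ("V", 0.14), ("F", 0.09), ("M", 0.05), ("W", 0.03), ("G", 0.03))
_C_BODY = (("A", 0.24), ("S", 0.20), ("T", 0.14), ("G", 0.10), ("P", 0.10), ("Q", 0.10), ("H", 0.05), ("E", 0.04), ("K", 0.03))
_MINUS3 = (("A", 0.70), ("V", 0.15), ("S", 0.10), ("T", 0.05))
_MINUS2 = (("K", 0.20), ("S", 0.20), ("Q", 0.15), ("E", 0.15), ("H", 0.10), ("F", 0.10), ("N", 0.10))
_MINUS1 = (("A", 0.85), ("S", 0.10), ("G", 0.05))
_AC = (("A", 0.20), ("E", 0.15), ("K", 0.15), ("S", 0.15), ("G", 0.15), ("D", 0.10), ("N", 0.10))


def _pick(pool, rng: np.random.Generator, size: int) -> str:
    residues = [aa for aa, _ in pool]
    probs = np.array([p for _, p in pool])
    return "".join(rng.choice(residues, size=size, p=probs / probs.sum()))


def generate_reference_set(
    n: int, rng: np.random.Generator, id_prefix: str = "ref"
) -> list[SPRecord]:
    """n valid tripartite SPRecords with realistic region composition."""
    if n < 1:
        raise ValueError("n must be >= 1")
    records = []
    for i in range(n):
        n_body = _pick(_N_BODY, rng, int(rng.integers(2, 8)))
        h_region = _pick(_H_CORE, rng, int(rng.integers(10, 16)))
        c_body = _pick(_C_BODY, rng, int(rng.integers(3, 7)))
        site = _pick(_MINUS3, rng, 1) + _pick(_MINUS2, rng, 1) + _pick(_MINUS1, rng, 1)
        ac = _pick(_AC, rng, 3)
        aa = "M" + n_body + h_region + c_body + site + ac
        rec = SPRecord(
            id=f"{id_prefix}_{i:04d}",
            aa_seq=aa,
            n_end=1 + len(n_body),
            h_end=1 + len(n_body) + len(h_region),
            c_end=len(aa) - 3,
        )
        records.append(rec.with_nt(_sample_codons(aa, rng)))
    return records


def _sample_codons(aa_seq: str, rng: np.random.Generator) -> str:
    """Codon-usage-weighted coding sequence (adds CAI/mfe variation)."""
    from .features.descriptors import _synonymous_families
    from .features.scales import codon_usage

    usage = codon_usage()
    families = _synonymous_families()
    parts = []
    for aa in aa_seq:
        codons = families[aa]
        probs = np.array([usage.get(c, 0.01) for c in codons])
        parts.append(str(rng.choice(list(codons), p=probs / probs.sum())))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Designed library: one feature edited at a time
# ---------------------------------------------------------------------------

DEFAULT_EDIT_SPECS = {
    "charge_N": (-2, -1, 1, 2),
    "hydrophobicity_H": (-3, -2, -1, 1, 2, 3),
    "length_H": (-2, -1, 1, 2),
    "cleavage_minus1": ("A", "S", "G", "V"),
}

_NEUTRAL_FOR_CHARGE = "SNQTG"
_HYDROPHILIC_IN_H = "AGST"
_HYDROPHOBIC_IN_H = "LIVF"


def _edit_charge_n(rec: SPRecord, level: int, rng: np.random.Generator) -> SPRecord | None:
    body = list(extract_region(rec, "N")[1:])
    if level > 0:
        targets = [i for i, aa in enumerate(body) if aa in _NEUTRAL_FOR_CHARGE]
        if len(targets) < level:
            return None
        for i in targets[:level]:
            body[i] = "K"
    else:
        targets = [i for i, aa in enumerate(body) if aa in "KR"]
        if len(targets) < -level:
            return None
        for i in targets[: -level]:
            body[i] = "S"
    aa = "M" + "".join(body) + rec.aa_seq[rec.n_end :]
    return replace(rec, aa_seq=aa, nt_seq=None)


def _edit_hydrophobicity_h(rec: SPRecord, level: int, rng: np.random.Generator) -> SPRecord | None:
    h = list(extract_region(rec, "H"))
    source = _HYDROPHILIC_IN_H if level > 0 else _HYDROPHOBIC_IN_H
    target = "L" if level > 0 else "A"
    idx = [i for i, aa in enumerate(h) if aa in source]
    if len(idx) < abs(level):
        return None
    for i in idx[: abs(level)]:
        h[i] = target
    aa = rec.aa_seq[: rec.n_end] + "".join(h) + rec.aa_seq[rec.h_end :]
    return replace(rec, aa_seq=aa, nt_seq=None)


def _edit_length_h(rec: SPRecord, level: int, rng: np.random.Generator) -> SPRecord | None:
    h = extract_region(rec, "H")
    if level > 0:
        h = h[: len(h) // 2] + "L" * level + h[len(h) // 2 :]
    else:
        if len(h) + level < 6:
            return None
        h = h[: len(h) + level]
    aa = rec.aa_seq[: rec.n_end] + h + rec.aa_seq[rec.h_end :]
    shift = len(h) - (rec.h_end - rec.n_end)
    return replace(
        rec, aa_seq=aa, h_end=rec.h_end + shift, c_end=rec.c_end + shift, nt_seq=None
    )


def _edit_cleavage_minus1(rec: SPRecord, level: str, rng: np.random.Generator) -> SPRecord | None:
    if rec.aa_seq[rec.c_end - 1] == level:
        return None
    aa = rec.aa_seq[: rec.c_end - 1] + level + rec.aa_seq[rec.c_end :]
    return replace(rec, aa_seq=aa, nt_seq=None)


_EDITORS: dict[str, Callable] = {
    "charge_N": _edit_charge_n,
    "hydrophobicity_H": _edit_hydrophobicity_h,
    "length_H": _edit_length_h,
    "cleavage_minus1": _edit_cleavage_minus1,
}


def generate_designed_library(
    reference: Sequence[SPRecord],
    edit_specs: dict | None = None,
    rng: np.random.Generator | None = None,
) -> list[SPRecord]:
    """Per reference SP and per (feature, level), one single-edit variant.

    Infeasible edits (e.g. removing more charge than the N-region carries)
    are skipped.  Variants are re-translated with usage-weighted codons.
    """
    edit_specs = edit_specs if edit_specs is not None else DEFAULT_EDIT_SPECS
    rng = rng or np.random.default_rng()
    unknown = set(edit_specs) - set(_EDITORS)
    if unknown:
        raise KeyError(f"unsupported edit specs: {sorted(unknown)}")
    library: list[SPRecord] = []
    for rec in reference:
        for feature_name, levels in edit_specs.items():
            for level in levels:
                variant = _EDITORS[feature_name](rec, level, rng)
                if variant is None:
                    continue
                variant = replace(
                    variant, id=f"{rec.id}|{feature_name}={level}"
                ).with_nt(_sample_codons(variant.aa_seq, rng))
                library.append(variant)
    return library


# ---------------------------------------------------------------------------
# Truth functions and the screen simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthFunction:
    """Named deterministic map from SP features to a true WA in [1, 10]."""

    name: str
    feature_names: tuple[str, ...]
    fn: Callable[[dict[str, float]], float]

    def __call__(self, rec: SPRecord) -> float:
        feats = {
            "GRAVY_SP": descriptors.compute_scale_feature(
                extract_region(rec, "SP"), _KD
            ),
            "Charge_N": descriptors.compute_net_charge(extract_region(rec, "N")),
            "-1_A": float(rec.aa_seq[rec.c_end - 1] == "A"),
        }
        return float(np.clip(self.fn(feats), 1.0, 10.0))


def _default_truth(feats: dict[str, float]) -> float:
    s = 0.5 + 1.2 * (feats["GRAVY_SP"] - 1.0) ** 2 - 0.4 * feats["Charge_N"] - 1.5 * feats["-1_A"]
    return 1.0 + 9.0 / (1.0 + np.exp(-s))


def _gravy_only_truth(feats: dict[str, float]) -> float:
    s = 1.5 * (feats["GRAVY_SP"] - 1.0) ** 2 - 1.0
    return 1.0 + 9.0 / (1.0 + np.exp(-s))


TRUTH_FUNCTIONS: dict[str, TruthFunction] = {
    "default": TruthFunction("default", ("GRAVY_SP", "Charge_N", "-1_A"), _default_truth),
    "gravy_only": TruthFunction("gravy_only", ("GRAVY_SP",), _gravy_only_truth),
}


@dataclass
class ScreenSimConfig:
    n_bins: int = 10
    reads_per_sp: int = 2000
    sigma: float = 1.0  # bin dispersion in WA units
    occupancy: Sequence[float] | None = None  # per-bin NLR counts

    def __post_init__(self):
        if self.n_bins < 2 or self.reads_per_sp < 1 or self.sigma <= 0:
            raise ValueError("ScreenSimConfig parameters must be positive")


def simulate_screen(
    sps: Sequence[SPRecord],
    truth: TruthFunction | str = "default",
    config: ScreenSimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BinCountTable, pd.Series]:
    """Multinomial bin counts around each SP's true WA, plus the truth map.

    Bin probabilities are a renormalized Gaussian evaluated at the bin
    indices, centered on the truth-function value; read probabilities are
    additionally proportional to per-bin NLR occupancy (so occupancy
    normalization is required to recover the truth).  The returned truth map
    holds each SP's expected binned WA (sum of bin values times bin
    probabilities) — the quantity the screen measures — which is a monotone,
    near-identity transform of the truth-function value away from the scale
    edges.
    """
    if isinstance(truth, str):
        truth = TRUTH_FUNCTIONS[truth]
    config = config or ScreenSimConfig()
    rng = rng or np.random.default_rng()
    bins = np.arange(1, config.n_bins + 1, dtype=float)
    occupancy = (
        np.asarray(config.occupancy, dtype=float)
        if config.occupancy is not None
        else rng.integers(800, 1201, size=config.n_bins).astype(float)
    )
    counts = np.zeros((len(sps), config.n_bins), dtype=float)
    true_wa = np.zeros(len(sps))
    for i, rec in enumerate(sps):
        center = truth(rec)
        p = np.exp(-0.5 * ((bins - center) / config.sigma) ** 2)
        p = p / p.sum()
        true_wa[i] = bins @ p  # expected binned WA: what the screen measures
        p_reads = p * occupancy
        counts[i] = rng.multinomial(config.reads_per_sp, p_reads / p_reads.sum())
    ids = [rec.id for rec in sps]
    table = BinCountTable(
        counts=pd.DataFrame(counts, index=ids, columns=[f"bin_{b}" for b in range(1, config.n_bins + 1)]),
        nlr_per_bin=pd.Series(occupancy, index=[f"bin_{b}" for b in range(1, config.n_bins + 1)]),
    )
    return table, pd.Series(true_wa, index=ids, name="true_wa")


def default_screen(
    n_sps: int = 500,
    reads_per_sp: int = 2000,
    sigma: float = 1.0,
    seed: int = 0,
    truth: str = "default",
) -> tuple[list[SPRecord], BinCountTable, pd.Series]:
    """The standard simulated study: reference set + designed library + screen.

    Reference SPs are generated first; the single-edit designed library is
    appended and the combined set is truncated to ``n_sps`` variants before
    the sort-seq simulation.
    """
    rng = np.random.default_rng(seed)
    n_ref = max(10, n_sps // 10)
    reference = generate_reference_set(n_ref, rng)
    library = generate_designed_library(reference, rng=rng)
    sps = (reference + library)[:n_sps]
    table, true_wa = simulate_screen(
        sps, truth=truth, config=ScreenSimConfig(reads_per_sp=reads_per_sp, sigma=sigma), rng=rng
    )
    return sps, table, true_wa
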