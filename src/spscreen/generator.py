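"""Pseudo-random signal-peptide generation with distribution matching.

From a reference set of tripartite SPs, seven residue-frequency dictionaries
are built (N-region body, H-region, C-region body, the -3/-2/-1 cleavage
positions, and the pooled Ac positions).  Region batches are sampled
independently from these dictionaries (uniform lengths over the configured
ranges), screened by per-feature two-sample Kolmogorov-Smirnov tests against
the reference (a batch is accepted when enough features have p > alpha),
juxtaposed into full SPs, length-filtered, and retro-translated with the
most-frequent-codon dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .features import descriptors, scales
from .records import SPRecord, extract_region

REGION_KINDS = ("N", "H", "C", "Ac")


@dataclass(frozen=True)
class FrequencyDictionaries:
    """Residue -> relative frequency maps for the seven generator scopes."""

    d_n: dict[str, float]
    d_h: dict[str, float]
    d_c: dict[str, float]
    d_m3: dict[str, float]
    d_m2: dict[str, float]
    d_m1: dict[str, float]
    d_ac: dict[str, float]

    def as_tuple(self):
        return (self.d_n, self.d_h, self.d_c, self.d_m3, self.d_m2, self.d_m1, self.d_ac)


@dataclass
class GeneratorConfig:
    batch_size: int = 10_000
    n_body_length: tuple[int, int] = (1, 10)  # plus the leading Met
    h_length: tuple[int, int] = (9, 16)
    c_body_length: tuple[int, int] = (4, 11)  # plus the -3/-2/-1 residues
    ac_length: int = 3
    ks_alpha: float = 0.1
    ks_min_pass: dict[str, int] = field(
        default_factory=lambda: {"N": 21, "H": 16, "C": 18, "Ac": 17}
    )
    max_total_length: int = 33  # assemblies of >= this many residues are discarded
    max_batch_attempts: int = 20


def _normalize_counts(counts: dict[str, int], scope: str) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no residues observed for dictionary scope {scope!r}")
    return {aa: c / total for aa, c in sorted(counts.items())}


def build_frequency_dictionaries(reference: Sequence[SPRecord]) -> FrequencyDictionaries:
    """Pool residue counts over the reference set, one dictionary per scope."""
    if not reference:
        raise ValueError("empty reference set")
    tallies: dict[str, dict[str, int]] = {k: {} for k in ("n", "h", "c", "m3", "m2", "m1", "ac")}

    def add(scope: str, residues: str) -> None:
        tally = tallies[scope]
        for aa in residues:
            tally[aa] = tally.get(aa, 0) + 1

    for rec in reference:
        add("n", extract_region(rec, "N")[1:])  # initial Met excluded
        add("h", extract_region(rec, "H"))
        c_region = extract_region(rec, "C")
        add("c", c_region[:-3])
        add("m3", c_region[-3])
        add("m2", c_region[-2])
        add("m1", c_region[-1])
        add("ac", extract_region(rec, "Ac"))
    return FrequencyDictionaries(
        d_n=_normalize_counts(tallies["n"], "N body"),
        d_h=_normalize_counts(tallies["h"], "H"),
        d_c=_normalize_counts(tallies["c"], "C body"),
        d_m3=_normalize_counts(tallies["m3"], "-3"),
        d_m2=_normalize_counts(tallies["m2"], "-2"),
        d_m1=_normalize_counts(tallies["m1"], "-1"),
        d_ac=_normalize_counts(tallies["ac"], "Ac"),
    )


def _draw(dictionary: Mapping[str, float], length: int, rng: np.random.Generator) -> str:
    residues = list(dictionary.keys())
    probs = np.array(list(dictionary.values()), dtype=float)
    probs = probs / probs.sum()
    return "".join(rng.choice(residues, size=length, p=probs)) if length else ""


def sample_region_batch(
    freqs: FrequencyDictionaries,
    kind: str,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Sample ``batch_size`` region strings for one region kind."""
    config = config or GeneratorConfig()
    rng = rng or np.random.default_rng()
    out: list[str] = []
    if kind == "N":
        lo, hi = config.n_body_length
        for _ in range(config.batch_size):
            out.append("M" + _draw(freqs.d_n, int(rng.integers(lo, hi + 1)), rng))
    elif kind == "H":
        lo, hi = config.h_length
        for _ in range(config.batch_size):
            out.append(_draw(freqs.d_h, int(rng.integers(lo, hi + 1)), rng))
    elif kind == "C":
        lo, hi = config.c_body_length
        for _ in range(config.batch_size):
            body = _draw(freqs.d_c, int(rng.integers(lo, hi + 1)), rng)
            site = _draw(freqs.d_m3, 1, rng) + _draw(freqs.d_m2, 1, rng) + _draw(freqs.d_m1, 1, rng)
            out.append(body + site)
    elif kind == "Ac":
        for _ in range(config.batch_size):
            out.append(_draw(freqs.d_ac, config.ac_length, rng))
    else:
        raise ValueError(f"unknown region kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov distribution matching
# ---------------------------------------------------------------------------

def two_sample_ks(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    D is the supremum of the absolute ECDF difference; the p-value comes from
    the Kolmogorov distribution at sqrt(n_eff) * D with effective size
    n_a * n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(kolmogorov(np.sqrt(n_eff) * d))
    return d, min(max(p, 0.0), 1.0)


_REGION_SCALES = (
    ("Gravy", "kyte_doolittle", "mean"),
    ("BomanInd", "boman", "mean"),
    ("Flexibility", "flexibility_vihinen", "mean"),
    ("Ez", "ez_insertion", "sum"),
)


def _composition_matrix(strings: Sequence[str]) -> np.ndarray:
    """(n_strings, 20) residue-count matrix in AMINO_ACIDS order."""
    index = {aa: i for i, aa in enumerate(descriptors.AMINO_ACIDS)}
    counts = np.zeros((len(strings), 20), dtype=float)
    for r, s in enumerate(strings):
        for aa in s:
            counts[r, index[aa]] += 1
    return counts


def _pi_from_counts(counts: np.ndarray, pka: dict[str, float], n_iter: int = 14) -> np.ndarray:
    """Vectorized bisection for the isoelectric point, composition-based."""
    idx = {aa: i for i, aa in enumerate(descriptors.AMINO_ACIDS)}

    def charge(ph: np.ndarray) -> np.ndarray:
        c = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"])) - 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
        for aa in "KRH":
            if aa in pka:
                c = c + counts[:, idx[aa]] / (1.0 + 10 ** (ph - pka[aa]))
        for aa in "DECY":
            if aa in pka:
                c = c - counts[:, idx[aa]] / (1.0 + 10 ** (pka[aa] - ph))
        return c

    lo = np.zeros(counts.shape[0])
    hi = np.full(counts.shape[0], 14.0)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        positive = charge(mid) > 0
        lo = np.where(positive, mid, lo)
        hi = np.where(positive, hi, mid)
    return 0.5 * (lo + hi)


def region_feature_table(strings: Sequence[str]) -> pd.DataFrame:
    """Per-sequence descriptors computable on a bare region string.

    27 features: length, four scale aggregates, net charge, pI and the 20
    residue frequencies — the default KS comparison list.  Every descriptor
    is composition-based, so the whole table is computed from one residue-
    count matrix.
    """
    counts = _composition_matrix(strings)
    lengths = counts.sum(axis=1)
    if np.any(lengths == 0):
        raise ValueError("empty region string")
    out = {"length": lengths}
    aas = descriptors.AMINO_ACIDS
    for prefix, table, agg in _REGION_SCALES:
        scale = scales.load_scale(table)
        vec = np.array([scale[aa] for aa in aas])
        total = counts @ vec
        out[prefix] = total if agg == "sum" else total / lengths
    idx = {aa: i for i, aa in enumerate(aas)}
    out["Charge"] = (counts[:, idx["R"]] + counts[:, idx["K"]]) - (
        counts[:, idx["D"]] + counts[:, idx["E"]]
    )
    out["pI"] = _pi_from_counts(counts, scales.pka_emboss())
    for aa in aas:
        out[f"freq_{aa}"] = counts[:, idx[aa]] / lengths
    return pd.DataFrame(out)


def accept_batch(
    batch: Sequence[str],
    reference: Sequence[SPRecord] | Sequence[str],
    kind: str,
    config: GeneratorConfig | None = None,
    features: Sequence[str] | None = None,
) -> tuple[bool, dict[str, float]]:
    """KS-compare batch vs reference feature distributions for one region.

    Accepts iff at least ``ks_min_pass[kind]`` features have p > ``ks_alpha``.
    """
    config = config or GeneratorConfig()
    if reference and isinstance(reference[0], SPRecord):
        ref_strings = [extract_region(rec, kind) for rec in reference]
    else:
        ref_strings = list(reference)
    batch_table = region_feature_table(batch)
    ref_table = region_feature_table(ref_strings)
    names = list(features) if features is not None else list(batch_table.columns)
    threshold = config.ks_min_pass[kind]
    if threshold > len(names):
        raise ValueError(
            f"ks_min_pass[{kind}]={threshold} exceeds the {len(names)} compared features"
        )
    p_values: dict[str, float] = {}
    for name in names:
        _, p = two_sample_ks(batch_table[name], ref_table[name])
        p_values[name] = p
    n_similar = sum(p > config.ks_alpha for p in p_values.values())
    return n_similar >= threshold, p_values


def generate_accepted_batch(
    freqs: FrequencyDictionaries,
    reference: Sequence[SPRecord],
    kind: str,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Sample region batches until one passes KS acceptance."""
    config = config or GeneratorConfig()
    rng = rng or np.random.default_rng()
    for _ in range(config.max_batch_attempts):
        batch = sample_region_batch(freqs, kind, config, rng)
        ok, _ = accept_batch(batch, reference, kind, config)
        if ok:
            return batch
    raise RuntimeError(
        f"no {kind}-region batch passed KS acceptance in {config.max_batch_attempts} attempts"
    )


def assemble_sps(
    n_batch: Sequence[str],
    h_batch: Sequence[str],
    c_batch: Sequence[str],
    ac_batch: Sequence[str],
    config: GeneratorConfig | None = None,
    id_prefix: str = "gen",
) -> list[SPRecord]:
    """Juxtapose region batches into SPRecords and apply the length filter.

    Assemblies whose length through the Ac region reaches
    ``max_total_length`` are discarded.
    """
    config = config or GeneratorConfig()
    sizes = {len(n_batch), len(h_batch), len(c_batch), len(ac_batch)}
    if len(sizes) != 1:
        raise ValueError("region batches must have equal sizes")
    records = []
    for i, (n, h, c, ac) in enumerate(zip(n_batch, h_batch, c_batch, ac_batch)):
        total = len(n) + len(h) + len(c) + len(ac)
        if total >= config.max_total_length:
            continue
        records.append(
            SPRecord(
                id=f"{id_prefix}_{i:05d}",
                aa_seq=n + h + c + ac,
                n_end=len(n),
                h_end=len(n) + len(h),
                c_end=len(n) + len(h) + len(c),
            )
        )
    return records


def retro_translate(
    aa_seq: str, codon_usage: Mapping[str, float] | None = None
) -> str:
    """Deterministic retro-translation with the most frequent codon per residue.

    Ties in codon frequency resolve to the lexicographically smallest codon;
    translating the output reproduces the input.
    """
    best = descriptors.most_frequent_codons(dict(codon_usage) if codon_usage else None)
    try:
        return "".join(best[aa] for aa in aa_seq)
    except KeyError as exc:
        raise KeyError(f"no codon entry for residue {exc.args[0]!r}") from exc


def design_candidates(
    reference: Sequence[SPRecord],
    model,
    encoder,
    n_select: int = 32,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    selected_features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate novel SPs and rank them by predicted WA (best secretors first).

    Runs the full loop: accepted region batches -> assembly -> length filter
    -> retro-translation -> feature encoding -> model prediction.  Returns a
    DataFrame (id, aa_seq, nt_seq, predicted_wa) sorted ascending by
    predicted WA, truncated to ``n_select`` rows.
    """
    config = config or GeneratorConfig()
    rng = rng or np.random.default_rng()
    freqs = build_frequency_dictionaries(reference)
    batches = {
        kind: generate_accepted_batch(freqs, reference, kind, config, rng)
        for kind in REGION_KINDS
    }
    records = assemble_sps(batches["N"], batches["H"], batches["C"], batches["Ac"], config)
    records = [r.with_nt(retro_translate(r.aa_seq)) for r in records]
    matrix = encoder.transform(records)
    if selected_features is not None:
        matrix = matrix[list(selected_features)]
    predictions = model.predict(matrix)
    out = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "aa_seq": [r.aa_seq for r in records],
            "nt_seq": [r.nt_seq for r in records],
            "n_end": [r.n_end for r in records],
            "h_end": [r.h_end for r in records],
            "c_end": [r.c_end for r in records],
            "predicted_wa": predictions,
        }
    ).sort_values(["predicted_wa", "id"], kind="mergesort")
    return out.head(n_select).reset_index(drop=True)
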