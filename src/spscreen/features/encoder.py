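"""SPFeatureEncoder: records -> feature matrix, as an sklearn transformer."""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ..records import SPRecord, cleavage_context, extract_region, validate_record
from . import descriptors, scales
from .catalog import FeatureCatalog, FeatureSpec, default_catalog


def rnafold_mfe(nt_seq: str) -> float:
    """Thermodynamic folding backend via the RNAfold command-line tool."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold not found on PATH")
    out = subprocess.run(
        [exe, "--noPS"], input=nt_seq + "\n", capture_output=True, text=True, check=True
    ).stdout
    # last line: "....structure.... ( -3.40)"
    tail = out.strip().splitlines()[-1]
    return float(tail[tail.rindex("(") + 1 : tail.rindex(")")])


class SPFeatureEncoder(TransformerMixin, BaseEstimator):
    """Compute the feature catalog for a batch of SPRecords.

    Parameters
    ----------
    catalog : FeatureCatalog or None
        Descriptors to compute; default: the shipped catalog.
    codon_usage : mapping or path or None
        Codon-usage reference for RSCU/CAI weights; default packaged table.
    mfe_backend : "nussinov" or callable
        Folding proxy for mfe features; a callable receives the nucleotide
        string and returns an energy-like value (e.g. ``rnafold_mfe``).
    scale_overrides : dict or None
        scale-name -> mapping, overriding packaged residue scales.
    validate : bool
        Check record invariants before encoding (recommended).
    """

    def __init__(
        self,
        catalog: FeatureCatalog | None = None,
        codon_usage: dict | str | None = None,
        mfe_backend: str | Callable[[str], float] = "nussinov",
        scale_overrides: dict | None = None,
        validate: bool = True,
    ):
        self.catalog = catalog
        self.codon_usage = codon_usage
        self.mfe_backend = mfe_backend
        self.scale_overrides = scale_overrides
        self.validate = validate

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, X: Sequence[SPRecord] | None = None, y=None) -> "SPFeatureEncoder":
        self.catalog_ = self.catalog if self.catalog is not None else default_catalog()
        usage = self.codon_usage
        if isinstance(usage, (str, Path)):
            usage = scales.load_scale(usage)
        self._usage = usage or scales.codon_usage()
        self._cai_weights = descriptors.rscu_weights(self._usage)
        self._scales: dict[str, dict[str, float]] = {}
        return self

    def get_feature_names_out(self, input_features=None):
        return list(self.catalog_.names)

    def _scale(self, name: str) -> dict[str, float]:
        if name not in self._scales:
            if self.scale_overrides and name in self.scale_overrides:
                self._scales[name] = dict(self.scale_overrides[name])
            else:
                self._scales[name] = scales.load_scale(name)
        return self._scales[name]

    # -- encoding -----------------------------------------------------------
    def _nt_region(self, rec: SPRecord, scope: str) -> str:
        bounds = {
            "N": (0, rec.n_end),
            "H": (rec.n_end, rec.h_end),
            "C": (rec.h_end, rec.c_end),
            "Ac": (rec.c_end, rec.c_end + 3),
            "SP": (0, rec.c_end),
        }[scope]
        return rec.nt_seq[3 * bounds[0] : 3 * bounds[1]]

    def _mfe(self, nt: str) -> float:
        if callable(self.mfe_backend):
            return float(self.mfe_backend(nt))
        return descriptors.compute_rna_mfe(nt)

    def _one_value(self, rec: SPRecord, spec: FeatureSpec, ctx: dict) -> float:
        if spec.needs_nt and rec.nt_seq is None:
            raise ValueError(
                f"feature {spec.name!r} requires a nucleotide sequence, "
                f"absent from record {rec.id!r}"
            )
        if spec.kind == "dummy":
            pos = spec.params["position"]
            observed = ctx["m3"] if pos == "-3" else ctx["m1"]
            return float(observed == spec.params["residue"])
        seq = ctx[spec.scope]
        if spec.kind == "scale-mean":
            return descriptors.compute_scale_feature(seq, self._scale(spec.params["scale"]))
        if spec.kind == "scale-sum":
            return descriptors.compute_scale_feature(
                seq, self._scale(spec.params["scale"]), aggregator="sum"
            )
        if spec.kind == "aa-frequency":
            return descriptors.compute_aa_frequency(seq, spec.params["residue"])
        if spec.kind == "net-charge":
            return descriptors.compute_net_charge(seq)
        if spec.kind == "pI":
            pka = self._scale(spec.params.get("pka", "pka_emboss"))
            return descriptors.compute_isoelectric_point(seq, pka)
        if spec.kind == "length":
            return float(len(seq))
        if spec.kind == "turn-indicator":
            return float(descriptors.compute_turn_indicator(ctx["C"][0]))
        if spec.kind == "cai":
            return descriptors.compute_cai(self._nt_region(rec, spec.scope), self._cai_weights)
        if spec.kind == "mfe":
            return self._mfe(self._nt_region(rec, spec.scope))
        if spec.kind == "mfe-downstream":
            window = int(spec.params.get("window", 50))
            end = min(3 * rec.c_end + window, len(rec.nt_seq))
            return self._mfe(rec.nt_seq[:end])
        raise ValueError(f"unknown feature kind {spec.kind!r}")  # pragma: no cover

    def encode_record(self, rec: SPRecord) -> dict[str, float]:
        """Feature vector for one record, aligned to the catalog order."""
        if self.validate:
            violations = validate_record(rec)
            if violations:
                raise ValueError(f"invalid record {rec.id!r}: {violations}")
        m3, _, m1 = cleavage_context(rec)
        ctx = {scope: extract_region(rec, scope) for scope in ("N", "H", "C", "Ac", "SP")}
        ctx.update(m3=m3, m1=m1)
        return {spec.name: self._one_value(rec, spec, ctx) for spec in self.catalog_}

    def transform(self, X: Sequence[SPRecord]) -> pd.DataFrame:
        if not hasattr(self, "catalog_"):
            self.fit()
        rows = [self.encode_record(rec) for rec in X]
        return pd.DataFrame(rows, index=[rec.id for rec in X], columns=self.catalog_.names)


def assemble_feature_vector(
    rec: SPRecord, catalog: FeatureCatalog | None = None, **encoder_kwargs
) -> dict[str, float]:
    """One-shot feature vector for a single record (thin wrapper)."""
    return SPFeatureEncoder(catalog=catalog, **encoder_kwargs).fit().encode_record(rec)


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="id")


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
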