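"""Feature catalog: named physicochemical descriptors per SP region.

The default catalog carries the descriptors named in the screen analysis
(GRAVY, Boman index, flexibility, Ez insertion potential, charge, pI, length,
per-region residue frequencies, the Turn_C helix-breaker indicator, CAI from
RSCU weights, folding-energy proxies) plus the 40 cleavage-site dummies.
Catalogs serialize to YAML and are fully user-extensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

from .descriptors import AMINO_ACIDS

SCOPES = ("N", "H", "C", "Ac", "SP")
KINDS = (
    "scale-mean",
    "scale-sum",
    "aa-frequency",
    "net-charge",
    "pI",
    "turn-indicator",
    "length",
    "cai",
    "mfe",
    "mfe-downstream",
    "dummy",
)


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    scope: str
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def needs_nt(self) -> bool:
        return self.kind in ("cai", "mfe", "mfe-downstream")


class FeatureCatalog:
    """Ordered, name-unique collection of FeatureSpecs."""

    def __init__(self, specs: list[FeatureSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        self.specs = list(specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self) -> Iterator[FeatureSpec]:
        return iter(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def dummy_names(self) -> list[str]:
        return [s.name for s in self.specs if s.kind == "dummy"]

    def to_yaml(self, path: str | Path) -> None:
        payload = [
            {"name": s.name, "scope": s.scope, "kind": s.kind, "params": s.params}
            for s in self.specs
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureCatalog":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            [
                FeatureSpec(
                    name=e["name"],
                    scope=e["scope"],
                    kind=e["kind"],
                    params=e.get("params") or {},
                )
                for e in payload
            ]
        )


def default_catalog(include_nt: bool = True, downstream_window: int = 50) -> FeatureCatalog:
    """The shipped catalog: 120 sequence descriptors (+40 dummies).

    Nucleotide-level descriptors (CAI, folding proxies) are included unless
    ``include_nt`` is false; they require records with a coding sequence.
    """
    specs: list[FeatureSpec] = []

    def scale(prefix: str, scope: str, table: str, agg: str = "mean") -> FeatureSpec:
        kind = "scale-mean" if agg == "mean" else "scale-sum"
        return FeatureSpec(f"{prefix}_{scope}", scope, kind, {"scale": table})

    specs.append(FeatureSpec("GRAVY_SP", "SP", "scale-mean", {"scale": "kyte_doolittle"}))
    for scope in ("N", "H", "C", "Ac"):
        specs.append(scale("Gravy", scope, "kyte_doolittle"))
    for scope in ("SP", "N", "H", "C", "Ac"):
        specs.append(scale("BomanInd", scope, "boman"))
    for scope in ("SP", "N", "H", "C"):
        specs.append(scale("Flexibility", scope, "flexibility_vihinen"))
    for scope in ("SP", "N", "H", "C", "Ac"):
        specs.append(scale("Ez", scope, "ez_insertion", agg="sum"))
    for scope in ("SP", "N", "H", "C", "Ac"):
        specs.append(FeatureSpec(f"Charge_{scope}", scope, "net-charge"))
    for scope in ("SP", "N", "H", "C", "Ac"):
        specs.append(FeatureSpec(f"pI_{scope}", scope, "pI", {"pka": "pka_emboss"}))
    for scope in ("SP", "N", "H", "C"):
        specs.append(FeatureSpec(f"Length_{scope}", scope, "length"))
    for scope in ("N", "H", "C", "Ac"):
        for aa in AMINO_ACIDS:
            specs.append(FeatureSpec(f"{aa}_{scope}", scope, "aa-frequency", {"residue": aa}))
    specs.append(FeatureSpec("Turn_C", "C", "turn-indicator"))
    if include_nt:
        specs.append(FeatureSpec("CAI_RSCU_SP", "SP", "cai"))
        for scope in ("SP", "N", "H", "C"):
            specs.append(FeatureSpec(f"Mfe_{scope}", scope, "mfe"))
        specs.append(
            FeatureSpec(
                "amyQ_mfe_SP", "SP", "mfe-downstream", {"window": downstream_window}
            )
        )
    for pos in ("-3", "-1"):
        for aa in AMINO_ACIDS:
            specs.append(FeatureSpec(f"{pos}_{aa}", "C", "dummy", {"position": pos, "residue": aa}))
    return FeatureCatalog(specs)
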