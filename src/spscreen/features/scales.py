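"""Packaged residue scales, pKa sets and codon-usage references.

All tables ship as two-column TSV data files and can be overridden by passing
an explicit mapping (or a path) to the functions that consume them.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

_DATA = resources.files("spscreen") / "data"


def load_scale(source: str | Path) -> dict[str, float]:
    """Read a two-column (key, value) TSV; '#' lines are comments.

    ``source`` may be the stem of a packaged table (e.g. ``"kyte_doolittle"``)
    or a filesystem path to a user-supplied table.
    """
    path = Path(str(source))
    if not path.suffix:
        text = (_DATA / f"{source}.tsv").read_text()
    else:
        text = path.read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key] = float(value)
    return table


@lru_cache(maxsize=None)
def _cached(stem: str) -> dict[str, float]:
    return load_scale(stem)


def kyte_doolittle() -> dict[str, float]:
    return dict(_cached("kyte_doolittle"))


def boman() -> dict[str, float]:
    return dict(_cached("boman"))


def flexibility() -> dict[str, float]:
    return dict(_cached("flexibility_vihinen"))


def ez_insertion() -> dict[str, float]:
    return dict(_cached("ez_insertion"))


def pka_emboss() -> dict[str, float]:
    return dict(_cached("pka_emboss"))


def codon_usage() -> dict[str, float]:
    """Default codon-usage reference (frequency per 1000 codons)."""
    return dict(_cached("codon_usage_bsubtilis"))
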