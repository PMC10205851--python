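"""Gene sets: named, ordered, duplicate-free lists of gene symbols.

Symbols are compared case-insensitively and stored uppercase throughout
the package.  Readers accept one-symbol-per-line TSV (first column) and
GMT (name, source, then symbols on one line).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from ._log import logger


def _normalize(symbols: Iterable[str]) -> list[str]:
    """Uppercase, strip, drop empties and duplicates keeping first occurrence."""
    seen: set[str] = set()
    out: list[str] = []
    for s in symbols:
        s = str(s).strip().upper()
        if s and s not in seen:
            seen.add(s)
            out.append(s)
    return out


@dataclass(frozen=True)
class GeneSet:
    """An ordered, unique, non-empty list of uppercase gene symbols."""

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        norm = _normalize(self.genes)
        if not norm:
            raise ValueError(f"gene set {self.name!r} is empty after normalization")
        object.__setattr__(self, "genes", tuple(norm))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).upper() in set(self.genes)

    def difference(self, other: "GeneSet | Iterable[str]") -> "GeneSet":
        """Set difference preserving this set's order."""
        drop = {s.upper() for s in other}
        kept = [g for g in self.genes if g not in drop]
        if not kept:
            raise ValueError(f"difference left gene set {self.name!r} empty")
        return GeneSet(self.name, tuple(kept), self.source)

    def intersection(self, other: "GeneSet | Iterable[str]") -> list[str]:
        keep = {s.upper() for s in other}
        return [g for g in self.genes if g in keep]


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gene_set(path: str | Path, format: str | None = None, name: str | None = None) -> GeneSet:
    """Read a gene set from a TSV (one symbol per line, first column) or GMT file.

    GMT: a single line ``name<TAB>source<TAB>gene1<TAB>gene2...``; if the
    file holds several GMT lines the first is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene set file not found: {path}")
    if format is None:
        format = "gmt" if path.suffix.lower().replace(".gz", "") == ".gmt" or ".gmt" in path.suffixes else "tsv"
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"gene set file {path} is empty")
    if format == "gmt":
        parts = lines[0].split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line in {path}: needs name, source, >=1 gene")
        return GeneSet(parts[0], tuple(parts[2:]), source=parts[1])
    genes = [ln.split("\t")[0] for ln in lines if not ln.startswith("#")]
    return GeneSet(name or path.stem, tuple(genes), source=str(path))


def write_gene_set(gs: GeneSet, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "gmt":
        path.write_text("\t".join([gs.name, gs.source or "."] + list(gs.genes)) + "\n")
    else:
        path.write_text("\n".join(gs.genes) + "\n")
    logger.info("stage=write_gene_set name=%s n=%d path=%s", gs.name, len(gs), path)


def bundled_gene_set(key: str) -> GeneSet:
    """Load one of the gene sets shipped with the package.

    Keys: ``s_phase``, ``g2m_phase`` (cell-cycle scoring lists),
    ``csc40`` (the 40-marker cancer-stem-cell vignette).
    """
    from importlib.resources import files

    fname = {
        "s_phase": "cell_cycle_s.txt",
        "g2m_phase": "cell_cycle_g2m.txt",
        "csc40": "csc_markers_40.txt",
    }[key]
    res = files("stemtyper.data").joinpath(fname)
    genes = [ln.split("\t")[0] for ln in res.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    return GeneSet(key, tuple(genes), source=f"bundled:{fname}")
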