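"""Genome assembly model: chromosome lengths and centromere intervals.

Assemblies are plain-text TSV tables (``chromosome``, ``length_bp``,
``centromere_start_bp``, ``centromere_end_bp``); hg19 and hg38 are bundled
as package resources, custom assemblies load from any path. Chromosome
names are stored without a ``chr`` prefix; lookups normalize the prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Chromosome",
    "GenomeAssembly",
    "AssemblyLookupError",
    "load_assembly",
    "get_assembly",
    "normalize_chromosome",
]

#: Default working chromosome set: autosomes + X. Y is excluded by default
#: (the target diseases are female cancers); pass ``include_y=True`` to keep it.
DEFAULT_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X",)


class AssemblyLookupError(KeyError):
    """Raised when a chromosome is not part of the assembly."""


def normalize_chromosome(name: object) -> str:
    """Strip an optional ``chr`` prefix and return the bare chromosome name."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    centromere_start_bp: int
    centromere_end_bp: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start_bp < self.centromere_end_bp < self.length_bp):
            raise ValueError(
                f"chromosome {self.name}: centromere interval "
                f"[{self.centromere_start_bp}, {self.centromere_end_bp}] must lie "
                f"strictly inside (0, {self.length_bp})"
            )


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered set of chromosomes with centromere annotations."""

    build_label: str
    chromosomes: tuple[Chromosome, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names in assembly")
        object.__setattr__(self, "_index", {c.name: c for c in self.chromosomes})

    def __contains__(self, name: object) -> bool:
        return normalize_chromosome(name) in self._index

    def __getitem__(self, name: object) -> Chromosome:
        key = normalize_chromosome(name)
        try:
            return self._index[key]
        except KeyError:
            raise AssemblyLookupError(
                f"chromosome {name!r} not in assembly {self.build_label!r} "
                f"(available: {', '.join(self._index)})"
            ) from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def subset(self, names: Iterable[str]) -> "GenomeAssembly":
        wanted = [normalize_chromosome(n) for n in names]
        return GenomeAssembly(self.build_label, tuple(self[n] for n in wanted))


def _from_frame(build_label: str, df: pd.DataFrame, include_y: bool) -> GenomeAssembly:
    required = {"chromosome", "length_bp", "centromere_start_bp", "centromere_end_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assembly table missing columns: {sorted(missing)}")
    chroms = []
    for row in df.itertuples(index=False):
        name = normalize_chromosome(row.chromosome)
        if name == "Y" and not include_y:
            continue
        chroms.append(
            Chromosome(
                name=name,
                length_bp=int(row.length_bp),
                centromere_start_bp=int(row.centromere_start_bp),
                centromere_end_bp=int(row.centromere_end_bp),
            )
        )
    return GenomeAssembly(build_label=build_label, chromosomes=tuple(chroms))


def load_assembly(path: str | Path, build_label: str = "custom", include_y: bool = True) -> GenomeAssembly:
    """Load a custom assembly from a TSV table."""
    df = pd.read_csv(path, sep="\t")
    return _from_frame(build_label, df, include_y=include_y)


def get_assembly(build: str, include_y: bool = False) -> GenomeAssembly:
    """Return a bundled assembly (``hg19`` or ``hg38``).

    Y is dropped unless ``include_y`` is set; autosomes + X is the default
    working set.
    """
    build = build.lower()
    if build not in ("hg19", "hg38"):
        raise AssemblyLookupError(f"unknown build {build!r}; bundled builds: hg19, hg38")
    ref = resources.files("hrdscar.data") / f"{build}.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return _from_frame(build, df, include_y=include_y)
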