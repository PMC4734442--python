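"""Read and write gene sets in the tab-delimited GMT format.

Each line is ``name <TAB> description <TAB> gene1 <TAB> gene2 ...``.
Gene order within a set is preserved on write; readers should treat
sets as unordered.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .biclustering import Bicluster, BiclusterRun


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    """Write ``{name: (description, genes)}`` to a GMT file."""
    with open(path, "w") as fh:
        for name, (description, genes) in sets.items():
            genes = list(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into ``{name: (description, genes)}``."""
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line")
            name, description, *genes = parts
            if name in out:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            out[name] = (description, genes)
    return out


def biclusters_to_gmt_sets(
    runs: Mapping[str, BiclusterRun]
) -> dict[str, tuple[str, list[str]]]:
    """Name biclusters ``bicluster_<k>_<direction>``; description = conditions."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for direction, run in runs.items():
        for k, bc in enumerate(run.biclusters, start=1):
            sets[f"bicluster_{k}_{direction}"] = (
                ",".join(bc.conditions),
                list(bc.genes),
            )
    return sets
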