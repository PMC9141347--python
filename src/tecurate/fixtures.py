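"""Packaged fixtures: the published per-genome TE coverage table and the two
phylogenetic presence/absence instances used for gain/loss analysis."""

from __future__ import annotations

from importlib import resources

from .io_formats import read_newick
from .tree import RootedTree


def _data_text(name: str) -> str:
    return resources.files("tecurate").joinpath(f"data/{name}").read_text()


def load_te_coverage_table() -> list[dict]:
    """The 20-row per-genome coverage table (lengths and covered bases in nt,
    percent with two decimals)."""
    lines = _data_text("apicomplexa_te_coverage.tsv").strip().splitlines()
    header = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        values = line.split("\t")
        row = dict(zip(header, values))
        row["assembly_length"] = int(row["assembly_length"])
        row["te_covered"] = int(row["te_covered"])
        row["te_percent"] = float(row["te_percent"])
        rows.append(row)
    return rows


def _load_instance(tree_name: str, presence_name: str) -> tuple[RootedTree, dict[str, bool]]:
    tree = read_newick(_data_text(tree_name))
    states = {}
    for line in _data_text(presence_name).strip().splitlines()[1:]:
        species, flag = line.split("\t")
        states[species] = flag == "1"
    return tree, states


def load_piroplasmid_instance() -> tuple[RootedTree, dict[str, bool]]:
    """Babesia/Theileria tree with LINE-like presence states."""
    return _load_instance("piroplasmids.nwk", "piroplasmids_presence.tsv")


def load_coccidian_instance() -> tuple[RootedTree, dict[str, bool]]:
    """Eimeriidae/Sarcocystidae tree with Gypsy-like presence states."""
    return _load_instance("coccidia.nwk", "coccidia_presence.tsv")
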