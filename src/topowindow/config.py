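"""Parameter profiles and topology alias bindings.

The default :class:`PipelineConfig` is the published parameter profile of
the analysis this package reproduces: 10-kb windows with >= 30 informative
columns, a strict 10% gap-ratio cutoff, the 0.05 composition-test level,
k >= 10 for "highly consecutive" runs, 500-kb genomic bins, 10,000
permutations of 295-tree blocks, 1% distance percentiles, and minimum run
lengths of 10 (introgressed) and 5 (resistant).  Any deviation from the
profile should be explicit in the caller.

Alias bindings attach short names (t1/t2/t3, tree-1/2/3) to canonical
topology strings so the classifier output is readable; they are built from
a role mapping (outgroup, donor pair, cherry pair, recipient) or loaded
from a YAML file, never hard-coded to one taxon system.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import yaml

from .treeio import TaxonSet
from .topology import _sort_nested, _nested_str, _nested_to_adjacency, _root_at

__all__ = [
    "PipelineConfig",
    "paper_defaults",
    "alias_bindings",
    "load_alias_bindings",
    "duck_taxa",
    "synthetic_taxa",
    "SYNTHETIC_ROLES",
    "DUCK_ROLES",
]

#: role -> label for the bundled synthetic six-lineage system
SYNTHETIC_ROLES = {
    "outgroup": "Outgroup",
    "donor_pair": ("DonorA", "DonorB"),
    "cherry_pair": ("TealX", "ShovelerX"),
    "recipient": "RecipientP",
}

#: role -> label for the six pruned duck taxa
DUCK_ROLES = {
    "outgroup": "Muscovy",
    "donor_pair": ("Steamer1", "Steamer2"),
    "cherry_pair": ("Baikal", "Shoveler"),
    "recipient": "Pekin",
}


@dataclass
class PipelineConfig:
    window_size: int = 10_000
    min_informative: int = 30
    max_gap: float = 0.10
    composition_alpha: float = 0.05
    apply_composition_max_window: int = 10_000  # composition test only <= this
    long_branch_factor: float = 5.0
    k_high: int = 10
    bin_size: int = 500_000
    perm_block: int = 295
    n_perm: int = 10_000
    intro_pct: float = 0.01
    intro_minrun: int = 10
    resist_pct: float = 0.01
    resist_minrun: int = 5
    seed: int = 0
    reference_taxon: str = "RecipientP"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def paper_defaults() -> PipelineConfig:
    """The published parameter profile (all dataclass defaults)."""
    return PipelineConfig()


def _canon(nested) -> str:
    return _nested_str(_sort_nested(nested)[1])


def alias_bindings(roles: dict | None = None) -> dict[str, str]:
    """t1/t2/t3 (and tree-1/2/3 synonyms) canonical strings for a role map.

    t1: donors outside, cherry with recipient (the species topology);
    t2: donors grouped with the recipient (the introgression topology);
    t3: donors grouped with the cherry.
    """
    roles = roles or SYNTHETIC_ROLES
    out = roles["outgroup"]
    d1, d2 = roles["donor_pair"]
    c1, c2 = roles["cherry_pair"]
    rec = roles["recipient"]
    shapes = {
        "t1": (out, (((c1, c2), rec), (d1, d2))),
        "t2": (out, ((c1, c2), (rec, (d1, d2)))),
        "t3": (out, (((c1, c2), (d1, d2)), rec)),
    }
    bindings = {alias: _canon(shape) for alias, shape in shapes.items()}
    for i in (1, 2, 3):
        bindings[f"tree-{i}"] = bindings[f"t{i}"]
    return bindings


def load_alias_bindings(path: str | Path | None = None) -> dict[str, str]:
    """Alias -> canonical-string map from a YAML file.

    Without a path, the bundled duck-system bindings are loaded.  The file
    holds an ``outgroup`` label and an ``aliases`` map whose values are
    branch-length-free newick-style shapes; each shape is rerooted on the
    outgroup and re-canonicalised on load, so the written rooting does not
    matter.
    """
    if path is None:
        source = (
            resources.files("topowindow") / "data" / "duck_aliases.yaml"
        ).read_text()
    else:
        source = Path(path).read_text()
    raw = yaml.safe_load(source)
    outgroup = raw["outgroup"]
    entries = raw["aliases"]

    def parse_nested(s: str):
        s = s.strip().rstrip(";")
        pos = 0

        def parse():
            nonlocal pos
            if s[pos] == "(":
                pos += 1
                kids = [parse()]
                while s[pos] == ",":
                    pos += 1
                    kids.append(parse())
                assert s[pos] == ")"
                pos += 1
                return tuple(kids)
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            return s[start:pos].strip()

        return parse()

    def reroot_canon(nested):
        adj = _nested_to_adjacency(nested)
        return _canon(_root_at(adj, outgroup))

    return {alias: reroot_canon(parse_nested(v)) for alias, v in entries.items()}


def duck_taxa() -> TaxonSet:
    r = DUCK_ROLES
    return TaxonSet(
        labels=(
            r["outgroup"], *r["donor_pair"], *r["cherry_pair"], r["recipient"]
        ),
        outgroup=r["outgroup"],
    )


def synthetic_taxa() -> TaxonSet:
    r = SYNTHETIC_ROLES
    return TaxonSet(
        labels=(
            r["outgroup"], *r["donor_pair"], *r["cherry_pair"], r["recipient"]
        ),
        outgroup=r["outgroup"],
    )
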