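"""Fossil calibrations, node constraints, and dating configurations.

Divergence-time estimation by penalized likelihood takes a tree with branch
lengths in substitutions plus a set of node age constraints.  Fossils
provide *minimum* ages: a fossil assignable to a clade constrains either
the clade's crown node (the MRCA of its sampled members) or its stem node
(the parent of that MRCA).  When several fossils land on the same node,
only the oldest is informative and the rest are superseded.  The root is
the one fixed-age node (min = max), and a single constraint outside the
focal group (stem euphyllophytes, 407.6 Ma minimum) anchors the backbone;
the default root age is 475 Ma (crown land plants).

The emitted configuration uses the treePL text dialect (``mrca``/``min``/
``max``/``smooth`` directives), one file per smoothing value over a sweep
grid (default 1e-12 .. 1e-06 by decades); the smoothing with the smallest
reported chi-squared is selected downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd

__all__ = [
    "FossilCalibration",
    "NodeConstraint",
    "TreePLConfig",
    "Assignment",
    "DEFAULT_ROOT_AGE",
    "DEFAULT_EUPHYLLOPHYTE_MIN",
    "DEFAULT_SMOOTHING_SWEEP",
    "root_and_trim",
    "assign_calibration_nodes",
    "resolve_redundant_calibrations",
    "build_constraints",
    "write_treepl_config",
    "parse_treepl_config",
    "validate_dated_tree",
    "collect_chisq",
    "read_calibrations",
    "write_calibrations",
]

DEFAULT_ROOT_AGE = 475.0  # Ma, crown land plants
DEFAULT_EUPHYLLOPHYTE_MIN = 407.6  # Ma, stem euphyllophytes
DEFAULT_SMOOTHING_SWEEP = tuple(10.0 ** -k for k in range(12, 5, -1))  # 1e-12 .. 1e-06


@dataclass(frozen=True)
class FossilCalibration:
    id: str
    fossil_name: str
    clade_name: str
    placement: str  # stem | crown
    anchor_taxa: tuple[str, ...]
    min_age: float
    period: str = ""
    citation: str = ""

    def __post_init__(self):
        if self.min_age <= 0:
            raise ValueError(f"{self.id}: min_age must be positive")
        if len(set(self.anchor_taxa)) != len(self.anchor_taxa):
            raise ValueError(f"{self.id}: anchor taxa must be distinct")
        if self.placement not in ("stem", "crown"):
            raise ValueError(f"{self.id}: placement must be stem or crown")


@dataclass(frozen=True)
class NodeConstraint:
    label: str
    mrca_pair: tuple[str, str]
    min_age: Optional[float] = None
    max_age: Optional[float] = None

    def __post_init__(self):
        if self.min_age is not None and self.max_age is not None:
            if self.min_age > self.max_age:
                raise ValueError(f"{self.label}: min_age > max_age")


@dataclass
class TreePLConfig:
    tree_file: str
    numsites: int
    constraints: list[NodeConstraint]
    smoothing: float
    options: tuple[str, ...] = ("thorough",)

    def __post_init__(self):
        if self.numsites < 1:
            raise ValueError("numsites must be >= 1")
        if self.smoothing <= 0:
            raise ValueError("smoothing must be positive")


@dataclass(frozen=True)
class Assignment:
    calibration: FossilCalibration
    node_leafset: frozenset[str]  # leaves under the constrained node


# ---------------------------------------------------------------------------
# Tree handling


def root_and_trim(tree: dendropy.Tree, outgroup_tip: str) -> dendropy.Tree:
    """Root on the outgroup edge, then remove the outgroup tip.

    Branch length between the outgroup attachment and the rest of the tree
    cannot be divided objectively, so the outgroup is discarded after
    rooting; tip-to-tip path lengths among retained tips are unchanged.
    """
    tree = tree.clone(depth=1)
    matches = [l for l in tree.leaf_node_iter() if l.taxon and l.taxon.label == outgroup_tip]
    if len(matches) != 1:
        raise ValueError(
            f"outgroup tip {outgroup_tip!r} occurs {len(matches)} times (need exactly 1)"
        )
    leaf = matches[0]
    tree.is_rooted = True
    tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    tree.prune_taxa([leaf.taxon], suppress_unifurcations=True)
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def _node_leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def assign_calibration_nodes(
    tree: dendropy.Tree,
    calibrations: Iterable[FossilCalibration],
) -> tuple[list[Assignment], list[tuple[FossilCalibration, str]]]:
    """Bind each calibration to a node of a rooted tree.

    Crown placement constrains the MRCA of the sampled anchor taxa; stem
    placement constrains that MRCA's parent (for a single sampled anchor,
    the tip's parent).  Calibrations with no sampled anchors, crown
    calibrations with fewer than two sampled anchors, or stem calibrations
    whose MRCA is the root are reported unassignable rather than dropped
    silently.
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted before calibration assignment")
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    assignments: list[Assignment] = []
    unassignable: list[tuple[FossilCalibration, str]] = []
    for cal in calibrations:
        present = sorted(set(cal.anchor_taxa) & tips)
        if not present:
            unassignable.append((cal, "missing_anchor"))
            continue
        if len(present) == 1:
            if cal.placement == "crown":
                unassignable.append((cal, "missing_anchor"))
                continue
            leaf = next(
                l for l in tree.leaf_node_iter() if l.taxon.label == present[0]
            )
            node = leaf.parent_node
        else:
            mrca = tree.mrca(taxon_labels=present)
            node = mrca.parent_node if cal.placement == "stem" else mrca
        if node is None:
            unassignable.append((cal, "stem_at_root"))
            continue
        assignments.append(Assignment(cal, _node_leafset(node)))
    return assignments, unassignable


def resolve_redundant_calibrations(
    assignments: Iterable[Assignment],
) -> tuple[list[Assignment], list[tuple[FossilCalibration, str]]]:
    """Per node, keep only the oldest calibration (ties: smallest id).

    Returns (kept, superseded) where each superseded calibration carries
    the winning calibration's id.
    """
    by_node: dict[frozenset[str], list[Assignment]] = {}
    for a in assignments:
        by_node.setdefault(a.node_leafset, []).append(a)
    kept: list[Assignment] = []
    superseded: list[tuple[FossilCalibration, str]] = []
    for node in sorted(by_node, key=lambda s: (len(s), sorted(s))):
        group = sorted(by_node[node], key=lambda a: (-a.calibration.min_age, a.calibration.id))
        kept.append(group[0])
        superseded.extend((a.calibration, group[0].calibration.id) for a in group[1:])
    return kept, superseded


# ---------------------------------------------------------------------------
# Constraint building and treePL config emission


def _sanitize_label(label: str) -> str:
    return re.sub(r"\W+", "_", label).strip("_")


def _pair_for_node(tree: dendropy.Tree, leafset: frozenset[str]) -> tuple[str, str]:
    """Two tips whose MRCA is the node with the given leafset."""
    if len(leafset) < 2:
        raise ValueError("cannot express a tip as an MRCA constraint")
    node = tree.mrca(taxon_labels=sorted(leafset))
    if _node_leafset(node) != leafset:
        raise ValueError("leafset does not correspond to a node of this tree")
    children = node.child_nodes()
    first = min(l.taxon.label for l in children[0].leaf_iter())
    second = min(l.taxon.label for l in children[-1].leaf_iter())
    return (first, second)


def build_constraints(
    tree: dendropy.Tree,
    assignments: Sequence[Assignment],
    fix_root: bool = True,
    root_age: float = DEFAULT_ROOT_AGE,
    euphyllophyte_anchors: Optional[tuple[str, str]] = None,
    euphyllophyte_min: float = DEFAULT_EUPHYLLOPHYTE_MIN,
) -> list[NodeConstraint]:
    """Node constraints from deduplicated assignments plus root/backbone anchors.

    The root is emitted with min = max = ``root_age`` when ``fix_root``;
    the stem-euphyllophyte minimum is emitted only when both its anchor
    tips are present in the tree.
    """
    constraints: list[NodeConstraint] = []
    if fix_root:
        root_set = _node_leafset(tree.seed_node)
        pair = _pair_for_node(tree, root_set)
        constraints.append(NodeConstraint("root", pair, root_age, root_age))
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    if euphyllophyte_anchors and set(euphyllophyte_anchors) <= tips:
        mrca = tree.mrca(taxon_labels=sorted(euphyllophyte_anchors))
        stem = mrca.parent_node
        if stem is not None:
            pair = _pair_for_node(tree, _node_leafset(stem))
            constraints.append(NodeConstraint("euphyllophytes_stem", pair, euphyllophyte_min))
    for a in assignments:
        pair = _pair_for_node(tree, a.node_leafset)
        constraints.append(
            NodeConstraint(_sanitize_label(a.calibration.id), pair, a.calibration.min_age)
        )
    if not constraints:
        raise ValueError("no_constraints: nothing to calibrate")
    return constraints


def write_treepl_config(
    constraints: Sequence[NodeConstraint],
    tree_file: str,
    numsites: int,
    smoothing_values: Sequence[float] = DEFAULT_SMOOTHING_SWEEP,
    tree_tips: Optional[set[str]] = None,
    options: Sequence[str] = ("thorough",),
    out_dir: Optional[str | Path] = None,
) -> dict[float, str]:
    """Emit one treePL config text per smoothing value.

    When ``tree_tips`` is given, every tip named in a constraint is checked
    against it before anything is written.
    """
    if not constraints:
        raise ValueError("no_constraints: nothing to calibrate")
    if tree_tips is not None:
        for c in constraints:
            missing = [t for t in c.mrca_pair if t not in tree_tips]
            if missing:
                raise ValueError(f"constraint {c.label}: tips absent from tree: {missing}")
    configs: dict[float, str] = {}
    for smooth in smoothing_values:
        lines = [f"treefile = {tree_file}", f"numsites = {numsites}"]
        for c in constraints:
            lines.append(f"mrca = {c.label} {c.mrca_pair[0]} {c.mrca_pair[1]}")
            if c.min_age is not None:
                lines.append(f"min = {c.label} {c.min_age:g}")
            if c.max_age is not None:
                lines.append(f"max = {c.label} {c.max_age:g}")
        lines.append(f"smooth = {smooth:g}")
        lines.extend(options)
        text = "\n".join(lines) + "\n"
        configs[smooth] = text
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / f"treepl_smooth_{smooth:.0e}.cfg").write_text(text)
    return configs


def parse_treepl_config(text: str) -> TreePLConfig:
    tree_file = ""
    numsites = 1
    smoothing = 1.0
    options: list[str] = []
    pairs: dict[str, tuple[str, str]] = {}
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    order: list[str] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if "=" in line:
            key, val = (p.strip() for p in line.split("=", 1))
            if key == "treefile":
                tree_file = val
            elif key == "numsites":
                numsites = int(val)
            elif key == "smooth":
                smoothing = float(val)
            elif key == "mrca":
                label, a, b = val.split()
                pairs[label] = (a, b)
                order.append(label)
            elif key == "min":
                label, age = val.split()
                mins[label] = float(age)
            elif key == "max":
                label, age = val.split()
                maxs[label] = float(age)
        else:
            options.append(line)
    constraints = [
        NodeConstraint(label, pairs[label], mins.get(label), maxs.get(label))
        for label in order
    ]
    return TreePLConfig(tree_file, numsites, constraints, smoothing, tuple(options))


# ---------------------------------------------------------------------------
# Validation of a dated tree against a config


def _node_age(node: dendropy.Node) -> float:
    best = 0.0
    for leaf in node.leaf_iter():
        d = 0.0
        cur = leaf
        while cur is not node:
            d += cur.edge.length or 0.0
            cur = cur.parent_node
        best = max(best, d)
    return best


def validate_dated_tree(
    dated_tree: dendropy.Tree,
    config: TreePLConfig,
    tol: float = 1e-6,
) -> list[tuple[str, str, float]]:
    """Check every constraint against node ages in a dated (ultrametric) tree.

    Returns (label, kind, observed age) for each violated constraint;
    empty list means the tree is admissible under the config.
    """
    violations = []
    for c in config.constraints:
        node = dated_tree.mrca(taxon_labels=list(c.mrca_pair))
        age = _node_age(node)
        if c.min_age is not None and age < c.min_age - tol:
            violations.append((c.label, "below_min", age))
        if c.max_age is not None and age > c.max_age + tol:
            violations.append((c.label, "above_max", age))
    return violations


def collect_chisq(run_outputs: dict[float, str]) -> tuple[Optional[float], dict[float, float]]:
    """Collect reported chi-squared values per smoothing run; flag the minimum."""
    values: dict[float, float] = {}
    for smooth, text in run_outputs.items():
        m = re.search(r"chisq\s*[:=]?\s*([-+0-9.eE]+)", text)
        if m:
            values[smooth] = float(m.group(1))
    best = min(values, key=lambda s: (values[s], s)) if values else None
    return best, values


# ---------------------------------------------------------------------------
# Calibration table I/O

_CAL_COLS = [
    "id", "fossil_name", "clade_name", "placement",
    "anchor1", "anchor2", "min_age", "period", "citation",
]


def read_calibrations(path: str | Path) -> list[FossilCalibration]:
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        anchors = tuple(a for a in (d.get("anchor1", ""), d.get("anchor2", "")) if a)
        out.append(
            FossilCalibration(
                id=d["id"],
                fossil_name=d.get("fossil_name", ""),
                clade_name=d.get("clade_name", ""),
                placement=d.get("placement", "crown"),
                anchor_taxa=anchors,
                min_age=float(d["min_age"]),
                period=d.get("period", ""),
                citation=d.get("citation", ""),
            )
        )
    return out


def write_calibrations(calibrations: Iterable[FossilCalibration], path: str | Path) -> None:
    rows = []
    for c in calibrations:
        anchors = list(c.anchor_taxa) + ["", ""]
        rows.append(
            {
                "id": c.id, "fossil_name": c.fossil_name, "clade_name": c.clade_name,
                "placement": c.placement, "anchor1": anchors[0], "anchor2": anchors[1],
                "min_age": c.min_age, "period": c.period, "citation": c.citation,
            }
        )
    pd.DataFrame(rows, columns=_CAL_COLS).to_csv(path, index=False)
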