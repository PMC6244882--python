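"""Sunburst hierarchy export and trend plots.

The sunburst is a prefix tree over pathway rounds: ring *k* shows the *k*-th
round, wedge sizes are patient counts. Depth defaults to 3 rings (the full
20-round tree is available by raising ``depth``). A patient whose pathway is
shorter than the display depth terminates at their final round; no placeholder
nodes are added, so leaf sizes always sum to the cohort size.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .pathway_extractor import PathwaySummary

__all__ = [
    "SunburstNode",
    "build_sunburst",
    "plot_trends",
    "subtree_size",
    "sunburst_to_dict",
    "write_sunburst_json",
]


@dataclasses.dataclass
class SunburstNode:
    """Node of the pathway prefix tree.

    ``size`` counts the patients whose (depth-truncated) pathway terminates at
    this node; ``None`` when no patient terminates here. Internal nodes may
    carry both a size and children.
    """

    name: str
    size: int | None = None
    children: list["SunburstNode"] = dataclasses.field(default_factory=list)


def subtree_size(node: SunburstNode) -> int:
    """Total patients passing through this node's prefix (sum of terminal sizes)."""
    return (node.size or 0) + sum(subtree_size(c) for c in node.children)


def build_sunburst(
    summary: PathwaySummary, depth: int = 3, names: Mapping[int, str] | None = None
) -> SunburstNode:
    """Build the prefix tree of pathway rounds, truncated at ``depth`` rings.

    Combination rounds are labelled with ``+``-joined ingredient labels. The
    root's subtree size equals the cohort size.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if summary.total_patients < 1:
        raise ValueError("empty pathway summary")
    label = (lambda i: names[i]) if names else str
    root = SunburstNode(name="root")
    for entry in summary.entries:
        node = root
        for round_ in entry.rounds[:depth]:
            name = "+".join(label(i) for i in sorted(round_))
            child = next((c for c in node.children if c.name == name), None)
            if child is None:
                child = SunburstNode(name=name)
                node.children.append(child)
            node = child
        node.size = (node.size or 0) + entry.count
    _sort(root)
    return root


def _sort(node: SunburstNode) -> None:
    node.children.sort(key=lambda c: (-subtree_size(c), c.name))
    for c in node.children:
        _sort(c)


def sunburst_to_dict(node: SunburstNode) -> dict:
    """Nested name/size/children dict consumable by d3 hierarchy layouts;
    childless ``children`` keys are pruned."""
    out: dict = {"name": node.name}
    if node.size is not None:
        out["size"] = node.size
    if node.children:
        out["children"] = [sunburst_to_dict(c) for c in node.children]
    return out


def write_sunburst_json(root: SunburstNode, path: str | Path) -> None:
    try:
        with open(path, "w") as fh:
            json.dump(sunburst_to_dict(root), fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write sunburst JSON to {path}: {exc}") from exc


def plot_trends(trends: pd.DataFrame, path: str | Path) -> None:
    """Three line charts (one per index) of proportion vs index year, one
    labelled series per disease. Proportions outside [0, 1] are rejected."""
    if trends.empty:
        raise ValueError("empty trend table")
    prop_cols = ["monotherapy_prop", "common_mono_prop", "first_line_prop"]
    for col in prop_cols:
        bad = ~trends[col].between(0.0, 1.0)
        if bad.any():
            raise ValueError(f"{col} outside [0, 1] in trend table rows {list(trends.index[bad])}")
    titles = {
        "monotherapy_prop": "Monotherapy",
        "common_mono_prop": "Most common drug as monotherapy",
        "first_line_prop": "Most common drug first-line",
    }
    fig, axes = plt.subplots(1, 3, figsize=(15, 4), sharey=True)
    for ax, col in zip(axes, prop_cols):
        for disease, grp in trends.groupby("disease"):
            grp = grp.sort_values("index_year")
            ax.plot(grp["index_year"], grp[col], marker="o", label=str(disease))
        ax.set_title(titles[col])
        ax.set_xlabel("index year")
        ax.set_ylim(0, 1)
        ax.legend()
    axes[0].set_ylabel("proportion of patients")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
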