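"""Serialisation of fitted decision trees.

A fitted tree is written as a directory: ``model.yaml`` (topology, breed
sets, per-node settings) plus ``arrays.npz`` holding the numeric payload
(singular vectors, column means, training coordinates) and per-node panel
TSVs.  Loading reconstructs a tree equivalent for classification.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import gio
from .pca import PCBasis, PCCoordinates
from .tree import TreeNode


def save_model(tree: TreeNode, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = list(tree.iter_nodes())
    index = {id(n): i for i, n in enumerate(nodes)}
    manifest = []
    arrays: dict[str, np.ndarray] = {}
    panel_dir = directory / "panels"
    for i, node in enumerate(nodes):
        entry = {
            "index": i,
            "name": str(node.name),
            "breeds": [str(b) for b in node.breeds],
            "children": [index[id(c)] for c in node.children],
            "k": None if node.k is None else int(node.k),
            "child_of_breed": {str(b): str(c) for b, c in node.child_of_breed.items()},
            "modes": sorted(node.bases),
            "has_panel": node.panel is not None,
        }
        manifest.append(entry)
        for mode, basis in node.bases.items():
            arrays[f"{i}:{mode}:V"] = basis.V
            arrays[f"{i}:{mode}:sigma"] = basis.sigma
            arrays[f"{i}:{mode}:means"] = basis.column_means
            arrays[f"{i}:{mode}:snp_ids"] = basis.snp_ids
            arrays[f"{i}:{mode}:coords"] = node.train_coords[mode].coords
        if node.bases:
            arrays[f"{i}:train_ids"] = np.asarray(node.train_coords[next(iter(node.bases))].sample_ids, dtype=str)
            arrays[f"{i}:train_breeds"] = np.asarray(node.train_breeds, dtype=str)
        if node.panel is not None:
            panel_dir.mkdir(exist_ok=True)
            gio.write_panel(node.panel, panel_dir / f"{node.name.replace(' ', '_').replace('/', '_')}.tsv")
            entry["tier_sizes"] = list(node.panel.tier_sizes)
            arrays[f"{i}:panel:snp_ids"] = node.panel.snp_ids
            arrays[f"{i}:panel:scores"] = node.panel.scores
    with open(directory / "model.yaml", "w") as fh:
        yaml.safe_dump({"nodes": manifest}, fh, sort_keys=False)
    np.savez(directory / "arrays.npz", **arrays)


def load_model(directory) -> TreeNode:
    directory = Path(directory)
    with open(directory / "model.yaml") as fh:
        manifest = yaml.safe_load(fh)["nodes"]
    data = np.load(directory / "arrays.npz", allow_pickle=False)
    nodes: list[TreeNode] = []
    for entry in manifest:
        i = entry["index"]
        node = TreeNode(name=entry["name"], breeds=tuple(entry["breeds"]), k=entry["k"])
        node.child_of_breed = dict(entry["child_of_breed"])
        for mode in entry["modes"]:
            basis = PCBasis(
                V=data[f"{i}:{mode}:V"],
                sigma=data[f"{i}:{mode}:sigma"],
                column_means=data[f"{i}:{mode}:means"],
                snp_ids=data[f"{i}:{mode}:snp_ids"],
            )
            node.bases[mode] = basis
            node.train_coords[mode] = PCCoordinates(
                coords=data[f"{i}:{mode}:coords"], sample_ids=data[f"{i}:train_ids"]
            )
        if entry["modes"]:
            node.basis = node.bases.get("full")
            node.train_breeds = data[f"{i}:train_breeds"]
            node.sample_ids = data[f"{i}:train_ids"]
        if entry.get("has_panel"):
            from .selection import SnpPanel

            node.panel = SnpPanel(
                node_name=entry["name"],
                snp_ids=data[f"{i}:panel:snp_ids"],
                tier_sizes=tuple(entry["tier_sizes"]),
                scores=data[f"{i}:panel:scores"],
            )
        nodes.append(node)
    for entry, node in zip(manifest, nodes):
        node.children = [nodes[j] for j in entry["children"]]
    return nodes[0]
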