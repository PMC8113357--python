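"""Neuronal morphology: SWC trees, depth normalization and morphometrics.

Reconstructions live in the standard 7-column SWC format.  The working
coordinate frame is soma-centred in x (slice width) and y (slice depth) and
pia-aligned in z (cortical depth): z = 0 at the pia, z = cortical thickness
at the white-matter border.  Two feature representations are computed per
cell: a 20-bin normalized depth histogram (z-profile) per compartment, and a
catalogue of scalar morphometrics.  No feature measures extent in the slice
depth (y) direction, which is distorted by shrinkage.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Morphology",
    "read_swc",
    "write_swc",
    "load_and_normalize",
    "resample_morphology",
    "smooth_neurites",
    "z_profile",
    "morphometrics",
    "MORPHOMETRIC_CATALOGUE",
    "filter_features_by_cv",
    "assign_layer",
    "DEFAULT_LAYER_BOUNDARIES",
]

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]
COMPARTMENT_TYPES = {"axon": (2,), "dendrite": (3, 4)}

#: Normalized layer boundaries (L1|L2/3, L2/3|L5, L5|L6) from Nissl staining.
DEFAULT_LAYER_BOUNDARIES = (0.07, 0.29, 0.73)
LAYER_NAMES = ("L1", "L2/3", "L5", "L6")


# --------------------------------------------------------------------------
# SWC I/O and the Morphology container
# --------------------------------------------------------------------------

def read_swc(source) -> pd.DataFrame:
    """Parse a 7-column SWC file (path, file object or string)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=r"\s+", comment="#", header=None,
                     names=SWC_COLUMNS)
    df["id"] = df["id"].astype(int)
    df["type"] = df["type"].astype(int)
    df["parent"] = df["parent"].astype(int)
    return df


def write_swc(nodes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + " ".join(SWC_COLUMNS) + "\n")
        for row in nodes.itertuples(index=False):
            fh.write(f"{int(row.id)} {int(row.type)} {row.x:.6f} {row.y:.6f} "
                     f"{row.z:.6f} {row.radius:.6f} {int(row.parent)}\n")


@dataclass
class Morphology:
    """Validated SWC node tree plus the cortical thickness of its slice."""

    nodes: pd.DataFrame
    cortical_thickness_um: float

    def __post_init__(self) -> None:
        if self.cortical_thickness_um <= 0:
            raise ValueError("cortical thickness must be positive")
        self.nodes = self.nodes.reset_index(drop=True)
        self._validate()
        self._index = {int(i): k for k, i in enumerate(self.nodes["id"])}
        self._children: dict[int, list[int]] = {int(i): [] for i in self.nodes["id"]}
        for nid, pid in zip(self.nodes["id"], self.nodes["parent"]):
            if pid != -1:
                self._children[int(pid)].append(int(nid))

    def _validate(self) -> None:
        roots = self.nodes[self.nodes["parent"] == -1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        ids = set(self.nodes["id"].astype(int))
        parents = set(self.nodes["parent"].astype(int)) - {-1}
        if not parents <= ids:
            raise ValueError("disconnected tree: parent ids missing")
        # cycle check via iterative parent walk
        parent_of = dict(zip(self.nodes["id"].astype(int),
                             self.nodes["parent"].astype(int)))
        for start in parent_of:
            seen = set()
            n = start
            while n != -1:
                if n in seen:
                    raise ValueError("cycle detected in SWC tree")
                seen.add(n)
                n = parent_of[n]

    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent"] == -1, "id"].iloc[0])

    @property
    def soma(self) -> pd.Series:
        return self.nodes.loc[self._index[self.root_id]]

    @property
    def soma_radius_um(self) -> float:
        return float(self.soma["radius"])

    @property
    def normalized_soma_depth(self) -> float:
        return float(self.soma["z"]) / self.cortical_thickness_um

    def children(self, nid: int) -> list[int]:
        return self._children[nid]

    def xyz(self, nid: int) -> np.ndarray:
        row = self.nodes.loc[self._index[nid]]
        return np.array([row["x"], row["y"], row["z"]], dtype=float)

    def node_type(self, nid: int) -> int:
        return int(self.nodes.loc[self._index[nid], "type"])

    def compartment_node_ids(self, compartment: str) -> list[int]:
        types = COMPARTMENT_TYPES[compartment]
        return [int(i) for i, t in zip(self.nodes["id"], self.nodes["type"])
                if t in types]

    def branches(self, compartment: str | None = None) -> list[list[int]]:
        """Unbranched node paths: each runs from the soma or a branch point
        to the next branch point or tip.  With ``compartment`` given, only
        paths through nodes of that type are returned (the path start may be
        the soma or a node of another type, serving as the anchor)."""
        types = COMPARTMENT_TYPES.get(compartment) if compartment else None
        paths: list[list[int]] = []

        def is_fork(nid: int) -> bool:
            return len(self._children[nid]) > 1 or nid == self.root_id

        for nid in self.nodes["id"].astype(int):
            parent = int(self.nodes.loc[self._index[nid], "parent"])
            if parent == -1:
                continue
            if types is not None and self.node_type(nid) not in types:
                continue
            # start a path at nodes whose parent is a fork, the root, or a
            # different compartment
            parent_other = (types is not None
                            and self.node_type(parent) not in types
                            and parent != self.root_id)
            if not (is_fork(parent) or parent_other):
                continue
            path = [parent, nid]
            cur = nid
            while True:
                kids = self._children[cur]
                if types is not None:
                    kids = [k for k in kids if self.node_type(k) in types]
                if len(kids) != 1 or len(self._children[cur]) > 1:
                    break
                cur = kids[0]
                path.append(cur)
            paths.append(path)
        return paths

    def path_points(self, path: list[int]) -> np.ndarray:
        return np.stack([self.xyz(n) for n in path])


# --------------------------------------------------------------------------
# Loading, resampling, smoothing
# --------------------------------------------------------------------------

def load_and_normalize(
    swc,
    cortical_thickness_um: float,
    soma_depth_normalized: float | None = None,
    depth_tolerance_um: float = 5.0,
) -> Morphology:
    """Load an SWC reconstruction into the pia-aligned frame.

    The soma is centred in x and y.  If ``soma_depth_normalized`` is given,
    z is shifted so the soma sits at that depth (pia at z = 0); otherwise z
    is assumed pia-aligned already.  Nodes above the pia beyond a small
    tolerance are rejected; nodes below the white matter are kept with a
    warning.
    """
    nodes = read_swc(swc) if not isinstance(swc, pd.DataFrame) else swc.copy()
    root = nodes[nodes["parent"] == -1]
    if len(root) != 1:
        raise ValueError("SWC must have exactly one root (soma)")
    sx, sy, sz = (float(root.iloc[0][c]) for c in ("x", "y", "z"))
    nodes["x"] -= sx
    nodes["y"] -= sy
    if soma_depth_normalized is not None:
        nodes["z"] += soma_depth_normalized * cortical_thickness_um - sz
    if (nodes["z"] < -depth_tolerance_um).any():
        raise ValueError("nodes above the pia after alignment")
    if (nodes["z"] > cortical_thickness_um).any():
        warnings.warn("nodes below the white-matter border; kept")
    return Morphology(nodes=nodes, cortical_thickness_um=cortical_thickness_um)


def resample_morphology(morph: Morphology, spacing_um: float = 1.0) -> Morphology:
    """New morphology with every branch resampled to at most ``spacing_um``
    point spacing (topology preserved; branch/fork nodes kept exactly)."""
    soma = morph.soma
    rows = [(1, int(soma["type"]), soma["x"], soma["y"], soma["z"],
             soma["radius"], -1)]
    new_id_of = {morph.root_id: 1}
    next_id = 2
    for path in morph.branches():
        pts = morph.path_points(path)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        n_new = max(int(np.ceil(total / spacing_um)), 1)
        s_new = np.linspace(0.0, total, n_new + 1)
        interp = np.stack([np.interp(s_new, arc, pts[:, k]) for k in range(3)], axis=1)
        swc_type = morph.node_type(path[1])
        radius = float(morph.nodes.loc[morph._index[path[1]], "radius"])
        parent_new = new_id_of[path[0]]
        for p in interp[1:]:
            rows.append((next_id, swc_type, p[0], p[1], p[2], radius, parent_new))
            parent_new = next_id
            next_id += 1
        new_id_of[path[-1]] = parent_new
    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    return Morphology(nodes=nodes, cortical_thickness_um=morph.cortical_thickness_um)


def smooth_neurites(
    morph: Morphology, window: int = 21, order: int = 3
) -> Morphology:
    """Savitzky-Golay smoothing of the slice-depth (y) coordinate per branch.

    Only y changes; x, z and topology are untouched.  Branches shorter than
    the window are mirror-padded to window length before filtering.
    """
    nodes = morph.nodes.copy()
    pos = {int(i): k for k, i in enumerate(nodes["id"])}
    for path in morph.branches():
        idx = [pos[n] for n in path[1:]]  # anchor node y belongs to parent path
        y = nodes.loc[idx, "y"].to_numpy(dtype=float)
        if y.size < 2:
            continue
        if y.size >= window:
            y_s = savgol_filter(y, window, order)
        else:
            pad = window - y.size
            left = pad // 2 + 1
            right = pad - pad // 2 + 1
            padded = np.concatenate([y[1:left][::-1], y, y[-right:-1][::-1]])
            if padded.size < window:
                continue
            y_s = savgol_filter(padded, window, order)[left - 1: left - 1 + y.size]
        nodes.loc[idx, "y"] = y_s
    return Morphology(nodes=nodes, cortical_thickness_um=morph.cortical_thickness_um)


# --------------------------------------------------------------------------
# z-profile
# --------------------------------------------------------------------------

def compartment_points(
    morph: Morphology, compartment: str, spacing_um: float = 1.0
) -> np.ndarray:
    """Resampled point cloud (N x 3) of one compartment's branches."""
    pts = []
    for path in morph.branches(compartment):
        p = morph.path_points(path)
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        if arc[-1] == 0:
            continue
        n_new = max(int(np.ceil(arc[-1] / spacing_um)), 1)
        s_new = np.linspace(0.0, arc[-1], n_new + 1)
        pts.append(np.stack(
            [np.interp(s_new, arc, p[:, k]) for k in range(3)], axis=1)[1:])
    if not pts:
        return np.empty((0, 3))
    return np.concatenate(pts)


def z_profile(
    morph: Morphology, compartment: str, n_bins: int = 20,
    spacing_um: float = 1.0,
) -> np.ndarray:
    """Normalized depth histogram of one compartment.

    The resampled point cloud is projected onto z, depths divided by the
    cortical thickness, and binned into ``n_bins`` equal bins spanning
    [0, 1] (half-open bins, last bin closed); the histogram is normalized to
    sum to 1.  An empty compartment yields the zero vector.
    """
    pts = compartment_points(morph, compartment, spacing_um)
    if pts.shape[0] == 0:
        return np.zeros(n_bins)
    depth = np.clip(pts[:, 2] / morph.cortical_thickness_um, 0.0, 1.0)
    hist, _ = np.histogram(depth, bins=n_bins, range=(0.0, 1.0))
    return hist / hist.sum()


# --------------------------------------------------------------------------
# Morphometrics
# --------------------------------------------------------------------------

def _branch_lengths(morph: Morphology, compartment: str) -> np.ndarray:
    out = []
    for path in morph.branches(compartment):
        p = morph.path_points(path)
        out.append(float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))))
    return np.asarray(out)


def _subtree_stats(morph: Morphology, node_ids: set[int]) -> dict[str, float]:
    """Core statistics over the branches whose non-anchor nodes lie in
    ``node_ids`` (a compartment or a subtree of one)."""
    nan = float("nan")
    if not node_ids:
        return {k: nan for k in (
            "total_length", "n_branch_points", "n_tips", "max_branch_order",
            "max_path_distance", "max_euclidean_distance", "x_extent",
            "z_extent", "width_height_log_ratio", "mean_branch_length",
            "sd_branch_length", "mean_tortuosity", "mean_bifurcation_angle")}
    soma_xyz = morph.xyz(morph.root_id)
    # path distances by walking from soma
    dist = {morph.root_id: 0.0}
    order = {morph.root_id: 0}
    stack = [morph.root_id]
    while stack:
        nid = stack.pop()
        for ch in morph.children(nid):
            step = float(np.linalg.norm(morph.xyz(ch) - morph.xyz(nid)))
            dist[ch] = dist[nid] + step
            order[ch] = order[nid] + (1 if len(morph.children(nid)) > 1 else 0)
            stack.append(ch)

    total = 0.0
    xs, zs, eucl, path_d = [], [], [], []
    n_tips = n_forks = 0
    max_order = 0
    angles = []
    for nid in node_ids:
        p = morph.xyz(nid)
        parent = int(morph.nodes.loc[morph._index[nid], "parent"])
        total += float(np.linalg.norm(p - morph.xyz(parent)))
        xs.append(p[0])
        zs.append(p[2])
        eucl.append(float(np.linalg.norm(p - soma_xyz)))
        path_d.append(dist[nid])
        kids = [k for k in morph.children(nid) if k in node_ids]
        if not kids:
            n_tips += 1
        if len(kids) > 1:
            n_forks += 1
            d1 = morph.xyz(kids[0]) - p
            d2 = morph.xyz(kids[1]) - p
            cosang = np.dot(d1, d2) / (np.linalg.norm(d1) * np.linalg.norm(d2))
            angles.append(float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
        max_order = max(max_order, order[nid])

    lens, torts = [], []
    for path in morph.branches():
        inner = [n for n in path[1:] if n in node_ids]
        if len(inner) != len(path) - 1:
            continue
        p = morph.path_points(path)
        arc = float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
        chord = float(np.linalg.norm(p[-1] - p[0]))
        lens.append(arc)
        if chord > 0:
            torts.append(arc / chord)

    x_extent = float(np.ptp(xs)) if len(xs) > 1 else 0.0
    z_extent = float(np.ptp(zs)) if len(zs) > 1 else 0.0
    whr = (float(np.log(x_extent / z_extent))
           if x_extent > 0 and z_extent > 0 else nan)
    return {
        "total_length": total,
        "n_branch_points": float(n_forks),
        "n_tips": float(n_tips),
        "max_branch_order": float(max_order),
        "max_path_distance": float(max(path_d)),
        "max_euclidean_distance": float(max(eucl)),
        "x_extent": x_extent,
        "z_extent": z_extent,
        "width_height_log_ratio": whr,
        "mean_branch_length": float(np.mean(lens)) if lens else nan,
        "sd_branch_length": float(np.std(lens)) if len(lens) > 1 else 0.0,
        "mean_tortuosity": float(np.mean(torts)) if torts else nan,
        "mean_bifurcation_angle": float(np.mean(angles)) if angles else nan,
    }


def _apical_subtree(morph: Morphology) -> set[int]:
    """Nodes of the dendritic stem with the longest total path length (the
    operational definition of the apical dendrite)."""
    dend_types = COMPARTMENT_TYPES["dendrite"]
    best: set[int] = set()
    best_len = -1.0
    for stem in morph.children(morph.root_id):
        if morph.node_type(stem) not in dend_types:
            continue
        sub = set()
        stack = [stem]
        while stack:
            nid = stack.pop()
            sub.add(nid)
            stack.extend(morph.children(nid))
        total = sum(
            float(np.linalg.norm(
                morph.xyz(n)
                - morph.xyz(int(morph.nodes.loc[morph._index[n], "parent"]))))
            for n in sub)
        if total > best_len:
            best_len, best = total, sub
    return best


def _axon_dendrite_overlap(morph: Morphology) -> float:
    """Histogram intersection of axonal and dendritic z-profiles in [0, 1]."""
    pa = z_profile(morph, "axon")
    pd_ = z_profile(morph, "dendrite")
    if pa.sum() == 0 or pd_.sum() == 0:
        return float("nan")
    return float(np.minimum(pa, pd_).sum())


#: compartment -> cell classes using it; 'apical'/'soma'/'overlap' are special.
MORPHOMETRIC_CATALOGUE: dict[str, tuple[str, ...]] = {
    "dendrite": ("excitatory", "inhibitory"),
    "axon": ("inhibitory",),
    "apical": ("excitatory",),
    "soma": ("excitatory", "inhibitory"),
    "overlap": ("inhibitory",),
}


def morphometrics(morph: Morphology, cell_class: str) -> dict[str, float]:
    """Scalar morphometrics for one cell.

    Excitatory cells get dendritic, apical-dendrite and somatic features
    (axons are too incompletely recovered to quantify); inhibitory cells get
    axonal, dendritic, somatic and axon-dendrite overlap features.  No
    feature measures extent along the slice-depth (y) axis.
    """
    if cell_class not in ("excitatory", "inhibitory"):
        raise ValueError("cell_class must be 'excitatory' or 'inhibitory'")
    out: dict[str, float] = {}
    for comp, classes in MORPHOMETRIC_CATALOGUE.items():
        if cell_class not in classes:
            continue
        if comp in ("axon", "dendrite"):
            ids = set(morph.compartment_node_ids(comp))
            stats = _subtree_stats(morph, ids)
            out.update({f"{comp}_{k}": v for k, v in stats.items()})
        elif comp == "apical":
            stats = _subtree_stats(morph, _apical_subtree(morph))
            keep = ("total_length", "max_path_distance", "z_extent", "x_extent",
                    "n_branch_points")
            out.update({f"apical_{k}": stats[k] for k in keep})
        elif comp == "soma":
            out["soma_radius"] = morph.soma_radius_um
            out["normalized_soma_depth"] = morph.normalized_soma_depth
        elif comp == "overlap":
            out["axon_dendrite_z_overlap"] = _axon_dendrite_overlap(morph)
    return out


def filter_features_by_cv(
    table: pd.DataFrame, threshold: float = 0.25
) -> tuple[pd.DataFrame, list[str]]:
    """Drop near-constant features: among strictly positive-valued columns,
    those with coefficient of variation below ``threshold`` are removed.
    Columns containing non-positive values are never dropped by this rule.
    """
    dropped = []
    for col in table.columns:
        vals = table[col].dropna().to_numpy(dtype=float)
        if vals.size == 0 or (vals <= 0).any():
            continue
        cv = np.std(vals) / np.mean(vals)
        if cv < threshold:
            dropped.append(col)
    return table.drop(columns=dropped), dropped


def assign_layer(
    normalized_depth: float,
    boundaries: tuple[float, ...] = DEFAULT_LAYER_BOUNDARIES,
) -> str:
    """Cortical layer from normalized soma depth; a depth exactly on a
    boundary goes to the deeper layer."""
    if not 0.0 <= normalized_depth <= 1.0:
        raise ValueError("normalized depth must lie in [0, 1]")
    if list(boundaries) != sorted(boundaries):
        raise ValueError("boundaries must be increasing")
    for b, name in zip(boundaries, LAYER_NAMES):
        if normalized_depth < b:
            return name
    return LAYER_NAMES[len(boundaries)]
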