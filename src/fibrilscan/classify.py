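"""Polymorph clustering and interpretable random-forest classification.

Normalized per-residue profiles from many fibril structures are compared
on their common residues.  Structure-level relationships come from Ward
clustering of per-structure mean profiles (Euclidean metric); the
classifier works at replicate level: residues are first agglomerated to
k=20 composite features (Ward feature agglomeration, each valued at the
member mean), a random forest (100 trees) is trained on a per-structure
replicate split (9 train / 26 test of 35 by default), the best of many
restarts is kept, and every prediction is decomposed exactly into a bias
plus per-cluster contributions by walking each tree's decision path.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial import distance_matrix as _euclidean_matrix
from sklearn.cluster import FeatureAgglomeration
from sklearn.ensemble import RandomForestClassifier

from .energetics import ScanResult
from .profiles import ResidueProfile  # noqa: F401  (public type in signatures)


# ---------------------------------------------------------------------------
# label mapping
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _subtype_table() -> dict[str, str]:
    path = resources.files("fibrilscan") / "data" / "subtype_parent_map.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return dict(zip(df["subtype"], df["parent"]))


_SUFFIX = re.compile(r"[-_](?:T\d+[a-z]?|PHF|SF)$")


def subtype_to_parent(structure_id: str) -> str:
    """Parent polymorph class for a structure label.

    Exact matches in the shipped (editable) table win; otherwise trailing
    subtype suffixes (``_T1``, ``-PHF``, ``-SF``, …) are stripped.
    """
    table = _subtype_table()
    if structure_id in table:
        return table[structure_id]
    out = structure_id
    while True:
        stripped = _SUFFIX.sub("", out)
        if stripped == out:
            return out
        out = stripped


# ---------------------------------------------------------------------------
# profile matrix
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    """Replicate × common-residue matrix of normalized ΔREU values."""

    values: pd.DataFrame  # index: MultiIndex (structure_id, replicate)
    labels: dict[str, str]  # structure_id -> parent class

    @property
    def residues(self) -> list:
        return list(self.values.columns)

    @property
    def structures(self) -> list[str]:
        return list(dict.fromkeys(self.values.index.get_level_values(0)))

    def structure_means(self) -> pd.DataFrame:
        return self.values.groupby(level=0, sort=False).mean()

    def row_labels(self) -> np.ndarray:
        return np.array([self.labels[s]
                         for s in self.values.index.get_level_values(0)])


def common_residue_intersection(profiles) -> ProfileMatrix:
    """One row per profile, columns = residues numeric in *all* profiles."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    common = set(profiles[0].non_na())
    for p in profiles[1:]:
        common &= set(p.non_na())
    if not common:
        raise ValueError("no residues are common to all profiles")
    cols = sorted(common)
    rows = {(p.structure_id, 0): [p.values[c] for c in cols]
            for p in profiles}
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    values.index = pd.MultiIndex.from_tuples(values.index,
                                             names=["structure_id", "replicate"])
    labels = {p.structure_id: subtype_to_parent(p.structure_id)
              for p in profiles}
    return ProfileMatrix(values=values, labels=labels)


def profile_matrix_from_scans(scans: list[ScanResult],
                              labels: dict[str, str] | None = None
                              ) -> ProfileMatrix:
    """Replicate-level matrix from scan results.

    Each replicate's per-residue ΔREU profile is min–max normalized per
    row, then restricted to residues scanned (non-excluded) in every
    structure.
    """
    per_scan_rows: dict[str, list[tuple[int, dict[int, float]]]] = {}
    common: set[int] | None = None
    for scan in scans:
        reps: dict[int, dict[int, float]] = {}
        for pos, ps in scan.positions.items():
            for rec in ps.records:
                reps.setdefault(rec.replicate, {})[pos] = rec.delta_reu_assembly
        # one normalization per structure: the replicate-mean profile sets
        # the min/max, and every replicate is mapped through that scale
        mean_prof = scan.mean_delta_reu()
        lo, hi = min(mean_prof.values()), max(mean_prof.values())
        span = (hi - lo) if hi > lo else 1.0
        norm_reps = []
        for rep, vals in sorted(reps.items()):
            norm_reps.append((rep, {p: 100.0 * (v - lo) / span
                                    for p, v in vals.items()}))
        per_scan_rows[scan.structure_id] = norm_reps
        scanned = set(scan.positions)
        common = scanned if common is None else (common & scanned)
    if not common:
        raise ValueError("no residues are common to all scans")
    cols = sorted(common)
    rows, index = [], []
    for sid, norm_reps in per_scan_rows.items():
        for rep, vals in norm_reps:
            rows.append([vals[c] for c in cols])
            index.append((sid, rep))
    values = pd.DataFrame(rows, columns=cols,
                          index=pd.MultiIndex.from_tuples(
                              index, names=["structure_id", "replicate"]))
    if labels is None:
        labels = {sid: subtype_to_parent(sid) for sid in per_scan_rows}
    return ProfileMatrix(values=values, labels=labels)


def distance_matrix(matrix: ProfileMatrix) -> pd.DataFrame:
    """Euclidean distances between per-structure mean profiles."""
    means = matrix.structure_means()
    d = _euclidean_matrix(means.values, means.values)
    return pd.DataFrame(d, index=means.index, columns=means.index)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class LinkageTree:
    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_ids: list[str]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def ward_cluster(matrix) -> LinkageTree:
    """Ward/Euclidean agglomeration of structures (or raw row vectors)."""
    if isinstance(matrix, ProfileMatrix):
        means = matrix.structure_means()
        X, ids = means.values, list(means.index)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(len(X))]
    if len(X) < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = linkage(X, method="ward")
    return LinkageTree(merges=Z, leaf_ids=ids)


def export_dendrogram(tree: LinkageTree, path) -> str:
    """Write the linkage tree as Newick with merge heights as node heights.

    Each branch length is the parent merge height minus the child's own
    height (leaves sit at height 0), so a two-leaf tree is ``(A:h,B:h);``.
    """
    n = len(tree.leaf_ids)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: tree.leaf_ids[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        node = n + k
        heights[node] = float(h)
        la = float(h) - heights[a]
        lb = float(h) - heights[b]
        newick[node] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
    text = newick[n + len(tree.merges) - 1] + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# feature agglomeration
# ---------------------------------------------------------------------------

@dataclass
class FeatureClustering:
    residue_to_cluster: dict[int, int]
    k: int

    def members(self, cluster: int) -> list[int]:
        return sorted(r for r, c in self.residue_to_cluster.items()
                      if c == cluster)


def agglomerate_features(matrix: ProfileMatrix, k: int = 20
                         ) -> tuple[FeatureClustering, ProfileMatrix]:
    """Merge covarying residue columns into k composite features.

    Ward/Euclidean agglomeration of columns; each reduced column is the
    mean of its member residues.  Reduced columns are named ``c<id>``.
    """
    ncol = len(matrix.residues)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ncol:
        raise ValueError(f"k={k} exceeds the {ncol} available residues")
    if k == ncol:
        mapping = {r: i for i, r in enumerate(matrix.residues)}
    else:
        agg = FeatureAgglomeration(n_clusters=k, metric="euclidean",
                                   linkage="ward")
        agg.fit(matrix.values.values)
        mapping = {r: int(c) for r, c in zip(matrix.residues, agg.labels_)}
    fc = FeatureClustering(residue_to_cluster=mapping, k=k)
    reduced = pd.DataFrame(index=matrix.values.index)
    for c in range(k):
        members = fc.members(c)
        reduced[f"c{c}"] = matrix.values[members].mean(axis=1)
    return fc, ProfileMatrix(values=reduced, labels=dict(matrix.labels))


# ---------------------------------------------------------------------------
# random forest protocol
# ---------------------------------------------------------------------------

@dataclass
class TrainProtocol:
    """Replicate-split protocol (train 9 / test 26 of 35 by default)."""

    n_train: int = 9
    n_test: int = 26
    n_restarts: int = 50  # published protocol used 2500
    n_trees: int = 100
    rng_seed: int = 0


@dataclass
class ClassifierReport:
    forest: RandomForestClassifier
    protocol: TrainProtocol
    best_restart: int
    test_accuracy: float
    feature_names: list[str]
    class_names: list[str]
    feature_clustering: FeatureClustering | None = None
    contributions: pd.DataFrame | None = None  # per structure, per cluster
    bias: np.ndarray | None = None


def _split_indices(matrix: ProfileMatrix, protocol: TrainProtocol,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    structure_of_row = matrix.values.index.get_level_values(0)
    train, test = [], []
    for sid in matrix.structures:
        rows = np.where(structure_of_row == sid)[0]
        if len(rows) < protocol.n_train + protocol.n_test:
            raise ValueError(
                f"structure {sid} has {len(rows)} replicates; the protocol "
                f"needs at least n_train+n_test = "
                f"{protocol.n_train + protocol.n_test} — lower n_train/n_test "
                f"or provide more replicates")
        perm = rng.permutation(rows)
        train.extend(perm[:protocol.n_train])
        test.extend(perm[protocol.n_train:protocol.n_train + protocol.n_test])
    return np.array(train), np.array(test)


def train_forest(matrix: ProfileMatrix,
                 protocol: TrainProtocol | None = None,
                 feature_clustering: FeatureClustering | None = None
                 ) -> ClassifierReport:
    """Best-of-restarts random forest on per-structure replicate splits.

    Each restart draws a fresh per-structure split of replicates into
    train/test, fits a forest on the train rows and scores held-out
    accuracy; the best-scoring restart is kept (ties go to the earlier
    restart).  Deterministic under the protocol seed.
    """
    protocol = protocol or TrainProtocol()
    y = matrix.row_labels()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 parent classes")
    X = matrix.values.values
    best = None
    for restart in range(protocol.n_restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence([protocol.rng_seed & 0x7FFFFFFF, restart]))
        tr, te = _split_indices(matrix, protocol, rng)
        clf = RandomForestClassifier(
            n_estimators=protocol.n_trees,
            random_state=int(rng.integers(2**31 - 1)))
        clf.fit(X[tr], y[tr])
        acc = float(clf.score(X[te], y[te]))
        if best is None or acc > best[0]:
            best = (acc, restart, clf)
    acc, restart, clf = best
    report = ClassifierReport(
        forest=clf, protocol=protocol, best_restart=restart,
        test_accuracy=acc, feature_names=list(matrix.values.columns),
        class_names=list(clf.classes_), feature_clustering=feature_clustering)
    # per-structure contribution of each cluster to the correct class,
    # evaluated on the replicate-mean profile of each structure
    means = matrix.structure_means()
    rows = {}
    bias_out = None
    for sid in means.index:
        bias, contrib = decompose_prediction(report, means.loc[sid].values)
        true_class = matrix.labels[sid]
        if true_class in report.class_names:
            ci = report.class_names.index(true_class)
            rows[sid] = contrib[:, ci]
            bias_out = bias
    report.contributions = pd.DataFrame.from_dict(
        rows, orient="index", columns=report.feature_names)
    report.bias = bias_out
    return report


def decompose_prediction(report, sample: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Exact decision-path decomposition of a forest prediction.

    Walks each tree from root to leaf, attributing the change in the
    node's class-probability vector at every split to the splitting
    feature, and averages over trees.  Returns ``(bias, contributions)``
    with shapes (n_classes,) and (n_features, n_classes); the identity
    ``bias + contributions.sum(axis=0) == predict_proba(sample)`` holds to
    floating-point round-off.
    """
    forest = report.forest if isinstance(report, ClassifierReport) else report
    x = np.asarray(sample, dtype=float).ravel()
    n_features = forest.n_features_in_
    if len(x) != n_features:
        raise ValueError(f"sample has {len(x)} features, forest expects "
                         f"{n_features}")
    n_classes = len(forest.classes_)
    bias = np.zeros(n_classes)
    contrib = np.zeros((n_features, n_classes))
    for est in forest.estimators_:
        t = est.tree_
        node = 0
        value = t.value[node][0]
        prob = value / value.sum()
        bias += prob
        while t.children_left[node] != -1:
            f = t.feature[node]
            node = (t.children_left[node] if x[f] <= t.threshold[node]
                    else t.children_right[node])
            value = t.value[node][0]
            new_prob = value / value.sum()
            contrib[f] += new_prob - prob
            prob = new_prob
    n = len(forest.estimators_)
    return bias / n, contrib / n
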