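"""Metabolomic concentration profiles: ingestion, group separation, clustering, PCA.

With only a handful of draws per group, conventional tests are out of reach;
the group-separation rule used here is the envelope criterion: a metabolite
separates two sample groups when one group's maximum concentration lies
strictly below the other group's minimum. Two-way hierarchical clustering
(UPGMA / unweighted average linkage, infinity-norm distance by default) and
PCA provide the qualitative sample-structure views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

#: Recognized sample group labels.
GROUP_LABELS = ("control", "patient_pre", "patient_post", "nonfasting", "other")

_NORM_METRIC = {"infinity": "chebyshev", "one": "cityblock", "two": "euclidean"}


@dataclass(frozen=True)
class ProfileTable:
    """A samples x metabolites concentration matrix (mM) with group labels."""

    data: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        data = self.data
        if data.isna().any().any():
            raise ValueError("profile table has missing cells; impute or drop first")
        if (data.values < 0).any():
            raise ValueError("negative concentration in profile table")
        if data.columns.has_duplicates:
            raise ValueError("duplicate metabolite names")
        if data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(map(str, data.index)) - set(self.groups)
        if missing:
            raise ValueError(f"samples missing from group map: {sorted(missing)}")
        object.__setattr__(self, "groups", dict(self.groups))

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def metabolites(self) -> list[str]:
        return [str(m) for m in self.data.columns]

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == label]

    def zscored(self) -> pd.DataFrame:
        """Column-wise z-scored copy of the matrix (off the default analysis path).

        Returned as a bare DataFrame because z-scores are signed and therefore
        not a valid concentration table.
        """
        data = self.data
        std = data.std(axis=0, ddof=1).replace(0.0, 1.0)
        return (data - data.mean(axis=0)) / std


def load_profiles(path, groups_path) -> ProfileTable:
    """Read a samples x metabolites TSV and a sample -> group TSV.

    Metabolite columns with any missing cell are dropped with a warning;
    negative concentrations and samples absent from the groups file are errors.
    """
    data = pd.read_csv(path, sep="\t", index_col=0)
    gtab = pd.read_csv(groups_path, sep="\t")
    if not {"sample", "group"}.issubset(gtab.columns):
        raise ValueError(f"groups file {groups_path} needs columns sample, group")
    groups = dict(zip(gtab["sample"].astype(str), gtab["group"].astype(str)))
    incomplete = [c for c in data.columns if data[c].isna().any()]
    if incomplete:
        warnings.warn(
            f"dropping metabolites with missing values: {sorted(map(str, incomplete))}"
        )
        data = data.drop(columns=incomplete)
    return ProfileTable(data=data, groups=groups)


def write_profiles(table: ProfileTable, path, groups_path) -> None:
    table.data.to_csv(path, sep="\t")
    pd.DataFrame(
        {"sample": list(table.groups), "group": list(table.groups.values())}
    ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Envelope separation rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaboliteGroups:
    """Metabolites separating two groups: elevated / depressed on the patient side."""

    high_set: frozenset[str]
    low_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.high_set & self.low_set:
            raise ValueError("high and low sets overlap")

    @property
    def total(self) -> int:
        return len(self.high_set) + len(self.low_set)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metabolite": m, "set": "high"} for m in sorted(self.high_set)]
        rows += [{"metabolite": m, "set": "low"} for m in sorted(self.low_set)]
        return pd.DataFrame(rows, columns=["metabolite", "set"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def separating_sets(
    profiles: ProfileTable,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> MetaboliteGroups:
    """Metabolites whose concentration envelopes do not overlap between groups.

    ``group_b`` is the patient-side group: ``high_set`` holds metabolites whose
    minimum over group_b strictly exceeds the maximum over group_a, ``low_set``
    those whose maximum over group_b lies strictly below the minimum over
    group_a. Ties break toward exclusion (strict inequalities).
    """
    a, b = set(group_a), set(group_b)
    if a & b:
        raise ValueError(f"groups overlap: {sorted(a & b)}")
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    missing = (a | b) - set(profiles.samples)
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)}")
    data_a = profiles.data.loc[sorted(a)]
    data_b = profiles.data.loc[sorted(b)]
    high = data_b.min(axis=0) > data_a.max(axis=0)
    low = data_b.max(axis=0) < data_a.min(axis=0)
    return MetaboliteGroups(
        high_set=frozenset(map(str, high.index[high])),
        low_set=frozenset(map(str, low.index[low])),
    )


# ---------------------------------------------------------------------------
# Two-way hierarchical clustering (UPGMA)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterResult:
    """UPGMA merge trees over samples (rows) and metabolites (columns)."""

    sample_linkage: np.ndarray
    metabolite_linkage: np.ndarray
    sample_labels: tuple[str, ...]
    metabolite_labels: tuple[str, ...]
    distance_norm: str
    linkage_method: str = "unweighted_average"

    def sample_merges(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """Merge sequence over samples as (members_left, members_right, height)."""
        return _merges(self.sample_linkage, self.sample_labels)

    def metabolite_merges(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        return _merges(self.metabolite_linkage, self.metabolite_labels)

    def sample_newick(self) -> str:
        """Newick serialization of the sample tree with merge heights as depths."""
        tree = to_tree(self.sample_linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.sample_labels[node.id].replace(" ", "_")
            left, right = render(node.get_left()), render(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:g},{right}:{dr:g})"

        return render(tree) + ";"

    def merges_to_tsv(self, path) -> None:
        rows = []
        for axis, merges in (
            ("sample", self.sample_merges()),
            ("metabolite", self.metabolite_merges()),
        ):
            for left, right, height in merges:
                rows.append(
                    {
                        "axis": axis,
                        "left": "|".join(sorted(left)),
                        "right": "|".join(sorted(right)),
                        "height": height,
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _merges(Z: np.ndarray, labels: tuple[str, ...]):
    clusters: dict[int, frozenset[str]] = {
        i: frozenset([label]) for i, label in enumerate(labels)
    }
    merges = []
    n = len(labels)
    for k, (i, j, height, _) in enumerate(Z):
        left, right = clusters[int(i)], clusters[int(j)]
        merges.append((left, right, float(height)))
        clusters[n + k] = left | right
    return merges


def two_way_cluster(
    profiles: ProfileTable,
    norm: str = "infinity",
    linkage: str = "unweighted_average",
) -> ClusterResult:
    """Cluster samples (rows) and metabolites (columns) with UPGMA.

    Distances are computed on raw concentrations under the chosen norm
    (``infinity`` -> Chebyshev, ``one`` -> city-block, ``two`` -> Euclidean);
    no normalization is applied by default (use :meth:`ProfileTable.zscored`
    explicitly for a scaled variant).
    """
    if norm not in _NORM_METRIC:
        raise ValueError(f"norm must be one of {sorted(_NORM_METRIC)}, got {norm!r}")
    if linkage != "unweighted_average":
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = profiles.data.values
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 metabolites to cluster")
    metric = _NORM_METRIC[norm]
    sample_Z = scipy_linkage(pdist(values, metric=metric), method="average")
    metabolite_Z = scipy_linkage(pdist(values.T, metric=metric), method="average")
    return ClusterResult(
        sample_linkage=sample_Z,
        metabolite_linkage=metabolite_Z,
        sample_labels=tuple(profiles.samples),
        metabolite_labels=tuple(profiles.metabolites),
        distance_norm=norm,
        linkage_method=linkage,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreTable:
    """Sample coordinates on the top principal components of the centered data."""

    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: tuple[float, ...]
    loadings: pd.DataFrame  # metabolites x components

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t")


def pca_scores(profiles: ProfileTable, k: int) -> ScoreTable:
    """Scores of the mean-centered profiles on the top-k principal components.

    Centering only, no variance scaling. Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is positive.
    """
    n_samples, n_mets = profiles.data.shape
    if not 1 <= k <= min(n_samples - 1, n_mets):
        raise ValueError(
            f"k={k} out of range [1, {min(n_samples - 1, n_mets)}] "
            f"for {n_samples} samples x {n_mets} metabolites"
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(profiles.data.values)
    components = pca.components_
    for comp in range(k):
        pivot = np.argmax(np.abs(components[comp]))
        if components[comp, pivot] < 0:
            components[comp] *= -1
            scores[:, comp] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    return ScoreTable(
        scores=pd.DataFrame(scores, index=profiles.data.index, columns=cols),
        explained_variance_ratio=tuple(float(f) for f in pca.explained_variance_ratio_),
        loadings=pd.DataFrame(components.T, index=profiles.data.columns, columns=cols),
    )
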