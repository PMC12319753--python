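"""Feature-production norms and cosine-similarity binning.

Between-object similarity is measured as the cosine of the angle between
feature-production-frequency vectors: each object is described by how many
norming participants produced each feature for it, and two objects are
similar to the extent that their feature vectors point in the same
direction.  Deviant objects are then assigned to four similarity bins per
adaptor — super-close (SC), close (C), distant (D) and super-distant (SD) —
which form the ordinal similarity axis of the release-from-adaptation
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Bin labels ordered from most to least similar to the adaptor.
BIN_LABELS = ("SC", "C", "D", "SD")

#: Deviant conditions including the Identity condition.
CONDITIONS = ("SC", "C", "D", "SD", "I")


@dataclass
class FeatureNormTable:
    """Objects x features matrix of feature production frequencies."""

    object_ids: list[str]
    feature_ids: list[str]
    freq: np.ndarray  # (n_objects, n_features) non-negative integers

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq)
        if len(self.object_ids) != len(set(self.object_ids)):
            raise ValueError("duplicate object labels in feature norms")
        if np.any(self.freq < 0):
            raise ValueError("negative production frequencies are invalid")
        if self.freq.shape != (len(self.object_ids), len(self.feature_ids)):
            raise ValueError("freq shape does not match object/feature labels")


@dataclass
class SimilarityMatrix:
    """Symmetric objects x objects cosine-similarity matrix, entries in [0, 1]."""

    values: np.ndarray
    object_ids: list[str]

    def sim(self, a: str, b: str) -> float:
        i = self.object_ids.index(a)
        j = self.object_ids.index(b)
        return float(self.values[i, j])


@dataclass
class SimilarityBinning:
    """One adaptor's deviant assignment: one deviant object per similarity bin."""

    adaptor_id: str
    deviants: dict[str, str]  # bin label -> deviant object id
    bin_edges: list[tuple[float, float]] = field(default_factory=list)


def load_feature_norms(path) -> FeatureNormTable:
    """Read a feature-norm CSV (first column object label, then feature counts).

    Missing cells are treated as a production frequency of zero.  Duplicate
    object labels and negative counts are hard errors.
    """
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate object labels in {path}: {dups}")
    freq = df.fillna(0).to_numpy()
    if np.any(freq < 0):
        raise ValueError(f"negative production frequencies in {path}")
    return FeatureNormTable(
        object_ids=[str(o) for o in df.index],
        feature_ids=[str(f) for f in df.columns],
        freq=np.rint(freq).astype(np.int64),
    )


def cosine_similarity_matrix(norms: FeatureNormTable) -> SimilarityMatrix:
    """Cosine similarity between every pair of object frequency vectors.

    values[i, j] = <f_i, f_j> / (||f_i|| ||f_j||).  Counts are non-negative,
    so all entries lie in [0, 1]; the diagonal is exactly 1.
    """
    freq = norms.freq.astype(float)
    row_norms = np.linalg.norm(freq, axis=1)
    zero = np.flatnonzero(row_norms == 0)
    if zero.size:
        bad = [norms.object_ids[i] for i in zero]
        raise ValueError(f"all-zero feature vector for object(s): {bad}")
    unit = freq / row_norms[:, None]
    values = unit @ unit.T
    np.clip(values, 0.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values=values, object_ids=list(norms.object_ids))


def default_bin_edges(sim: SimilarityMatrix) -> list[tuple[float, float]]:
    """Quartile cut points of the off-diagonal similarity distribution.

    Returns four half-open intervals [lo, hi) ordered SC, C, D, SD (most to
    least similar); the SC interval is closed above so the maximum
    off-diagonal similarity is binnable.
    """
    n = len(sim.object_ids)
    off = sim.values[~np.eye(n, dtype=bool)]
    q = np.quantile(off, [0.0, 0.25, 0.5, 0.75, 1.0])
    # ordered most-similar first: SC = [q3, max], ..., SD = [min, q1)
    return [
        (float(q[3]), float(np.nextafter(q[4], np.inf))),
        (float(q[2]), float(q[3])),
        (float(q[1]), float(q[2])),
        (float(q[0]), float(q[1])),
    ]


def assign_bins(
    sim: SimilarityMatrix,
    adaptors: list[str],
    bin_edges: list[tuple[float, float]] | None = None,
    seed: int | None = None,
) -> list[SimilarityBinning]:
    """Pick one deviant per similarity bin for each adaptor.

    Candidates for a bin are the objects (excluding the adaptor) whose
    similarity to the adaptor falls in the bin's half-open interval
    [lo, hi); ties at an edge therefore go to the lower-similarity bin.
    One candidate is sampled uniformly per bin under ``seed``, subject to
    the strict ordering sim(SC) > sim(C) > sim(D) > sim(SD).
    """
    if bin_edges is None:
        bin_edges = default_bin_edges(sim)
    if len(bin_edges) != 4:
        raise ValueError("exactly four bin intervals are required")
    rng = np.random.default_rng(seed)
    out = []
    for adaptor in adaptors:
        if adaptor not in sim.object_ids:
            raise KeyError(f"adaptor {adaptor!r} not in similarity matrix")
        i = sim.object_ids.index(adaptor)
        sims = sim.values[i]
        chosen: dict[str, str] = {}
        prev_sim = np.inf
        for label, (lo, hi) in zip(BIN_LABELS, bin_edges):
            cands = [
                j
                for j in range(len(sim.object_ids))
                if j != i and lo <= sims[j] < hi and sims[j] < prev_sim
            ]
            if not cands:
                raise ValueError(
                    f"no candidate deviant for adaptor {adaptor!r} in bin {label}"
                )
            j = cands[rng.integers(len(cands))]
            chosen[label] = sim.object_ids[j]
            prev_sim = sims[j]
        out.append(
            SimilarityBinning(adaptor_id=adaptor, deviants=chosen, bin_edges=list(bin_edges))
        )
    return out


def synthetic_feature_norms(
    n_families: int = 10,
    objects_per_family: int = 8,
    seed: int | None = None,
) -> FeatureNormTable:
    """Synthetic feature-production norms with a planted similarity structure.

    Objects come in families sharing high-frequency features; pairs of
    families share mid-frequency "group" features and everything shares a
    few low-frequency global features.  The resulting cosine similarities
    spread over all four quartile bins, so every family head can serve as
    an adaptor with candidates in each bin.  This is a synthetic stand-in
    for empirically collected norms, not a model of feature elicitation.
    """
    rng = np.random.default_rng(seed)
    fam_feats, group_feats, glob_feats = 6, 6, 12
    n_groups = (n_families + 1) // 2
    n_features = n_families * fam_feats + n_groups * group_feats + glob_feats
    n_objects = n_families * objects_per_family
    freq = np.zeros((n_objects, n_features), dtype=np.int64)
    for fam in range(n_families):
        rows = slice(fam * objects_per_family, (fam + 1) * objects_per_family)
        f0 = fam * fam_feats
        freq[rows, f0:f0 + fam_feats] = rng.poisson(30, (objects_per_family, fam_feats))
        g0 = n_families * fam_feats + (fam // 2) * group_feats
        freq[rows, g0:g0 + group_feats] = rng.poisson(12, (objects_per_family, group_feats))
    freq[:, -glob_feats:] = rng.poisson(3, (n_objects, glob_feats))
    freq += rng.poisson(0.5, freq.shape)
    object_ids = [f"obj{fam:02d}_{k}" for fam in range(n_families)
                  for k in range(objects_per_family)]
    feature_ids = [f"feat{j:03d}" for j in range(n_features)]
    return FeatureNormTable(object_ids=object_ids, feature_ids=feature_ids, freq=freq)


def write_similarity_csv(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.values, index=sim.object_ids, columns=sim.object_ids).to_csv(path)


def write_binning_tsv(binnings: list[SimilarityBinning], sim: SimilarityMatrix, path) -> None:
    rows = [
        {
            "adaptor": b.adaptor_id,
            "bin": label,
            "deviant": b.deviants[label],
            "similarity": sim.sim(b.adaptor_id, b.deviants[label]),
        }
        for b in binnings
        for label in BIN_LABELS
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
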