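"""ACS-anchored origin windows, aggregate profiles and k-means classes.

Every origin window spans [-600, +600] around the ACS midpoint and is
oriented so the T-rich ACS strand reads left to right; windows too close
to a chromosome end are excluded (logged, not raised).  Origins are
clustered on their window vectors with Euclidean k-means and the classes
are relabeled 1..k by strictly decreasing class-mean NDR width, the
field's ordering convention (class 1 = broadest NDR).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .coverage import CoverageTrack
from .io import OriginRecord
from . import ndr as ndr_mod

logger = logging.getLogger("orichrom.architecture")

DEFAULT_HALFWIDTH = 600
DEFAULT_K = 6
DEFAULT_ITERATIONS = 10_000
DEFAULT_RESTARTS = 8


@dataclass
class OriginProfileMatrix:
    """Oriented origin windows: rows = origins, columns = offsets."""

    data: pd.DataFrame  # index: origin names; columns: int offsets -hw..hw

    @property
    def halfwidth(self) -> int:
        return int(self.data.columns.max())

    @property
    def origin_names(self) -> list[str]:
        return list(self.data.index)

    def subset(self, names: list[str]) -> "OriginProfileMatrix":
        return OriginProfileMatrix(self.data.loc[names])


@dataclass
class ClassAssignment:
    """k-means classes ordered by descending mean NDR width."""

    labels: dict[str, int]            # origin name -> class id 1..k
    class_centroids: pd.DataFrame     # index: class id; columns: offsets
    class_mean_ndr_width: dict[int, float]  # NaN when every member is closed

    @property
    def k(self) -> int:
        return len(self.class_centroids)

    def members(self, class_id: int) -> list[str]:
        return [n for n, c in self.labels.items() if c == class_id]


def extract_origin_window(
    track: CoverageTrack, origin: OriginRecord, halfwidth: int = DEFAULT_HALFWIDTH
) -> np.ndarray | None:
    """Oriented signal over [-halfwidth, +halfwidth] around the ACS midpoint.

    Returns ``None`` (with a log line) when the window would run off a
    chromosome end.  For a minus-strand ACS the vector is reversed so
    the T-rich strand reads left to right.
    """
    values = track.values[origin.chrom]
    mid = origin.acs_mid
    if mid - halfwidth < 0 or mid + halfwidth >= len(values):
        logger.info(
            "origin %s excluded: ACS %d bp from a chromosome end (< %d)",
            origin.name, min(mid, len(values) - 1 - mid), halfwidth,
        )
        return None
    window = values[mid - halfwidth : mid + halfwidth + 1].copy()
    if origin.acs_strand == "-":
        window = window[::-1]
    return window


def build_profile_matrix(
    track: CoverageTrack,
    origins: list[OriginRecord],
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> OriginProfileMatrix:
    rows: dict[str, np.ndarray] = {}
    for origin in origins:
        window = extract_origin_window(track, origin, halfwidth)
        if window is not None:
            rows[origin.name] = window
    if not rows:
        raise ValueError("no origin windows could be extracted")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = np.arange(-halfwidth, halfwidth + 1)
    return OriginProfileMatrix(df)


def aggregate_profile(
    matrix: OriginProfileMatrix, subset: list[str] | None = None
) -> np.ndarray:
    """Column-wise mean profile over ``subset`` (default: all rows)."""
    df = matrix.data if subset is None else matrix.data.loc[subset]
    if len(df) == 0:
        raise ValueError("aggregate_profile over an empty origin subset")
    return df.to_numpy().mean(axis=0)


def window_ndr_width(
    profile: np.ndarray,
    halfwidth: int = DEFAULT_HALFWIDTH,
    min_len: int = ndr_mod.DEFAULT_MIN_LEN,
    threshold: float = ndr_mod.DEFAULT_THRESHOLD,
) -> float:
    """NDR width measured inside a single oriented window.

    Applies the genome-wide NDR rule to the window vector and returns
    the width of the qualifying run nearest the ACS (offset 0), or NaN
    when the window holds no NDR ('closed').
    """
    below = profile < threshold
    padded = np.concatenate(([False], below, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    best_width, best_dist = np.nan, np.inf
    for s, e in zip(edges[0::2].tolist(), edges[1::2].tolist()):
        if e - s < min_len:
            continue
        dist = max(s - halfwidth, halfwidth - (e - 1), 0)  # distance to offset 0
        if dist < best_dist:
            best_dist, best_width = dist, float(e - s)
    return best_width


def cluster_origin_profiles(
    matrix: OriginProfileMatrix,
    k: int = DEFAULT_K,
    iterations: int = DEFAULT_ITERATIONS,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    ndr_widths: dict[str, float] | None = None,
) -> ClassAssignment:
    """Euclidean k-means over origin window vectors.

    Best of ``restarts`` seeded initializations by within-cluster sum of
    squares, with an iteration budget of ``iterations`` per run.  Empty
    clusters (degenerate inputs) are dropped with a warning, and the
    surviving classes are relabeled so class-mean NDR width decreases
    from class 1 to class k (ties broken toward the larger class).
    ``ndr_widths`` may supply per-origin widths (e.g. from genome-wide
    NDR calls); otherwise widths are measured inside each window.
    """
    X = matrix.data.to_numpy()
    names = matrix.origin_names
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} available origin profiles")
    km = KMeans(
        n_clusters=k, n_init=restarts, max_iter=iterations,
        random_state=seed, algorithm="lloyd",
    )
    with warnings.catch_warnings():
        # duplicate rows legitimately collapse clusters; we handle that below
        warnings.filterwarnings("ignore", message=".*distinct clusters.*")
        raw_labels = km.fit_predict(X)
    populated = np.unique(raw_labels)
    if len(populated) < k:
        logger.warning(
            "degenerate clustering: only %d of %d classes populated", len(populated), k
        )
    hw = matrix.halfwidth
    if ndr_widths is None:
        widths = {n: window_ndr_width(X[i], halfwidth=hw) for i, n in enumerate(names)}
    else:
        widths = {
            n: (float(w) if isinstance(w, (int, float)) else np.nan)
            for n, w in ndr_widths.items()
        }
    # order surviving clusters by descending mean width, ties -> larger first
    stats = []
    for c in populated:
        members = [names[i] for i in np.flatnonzero(raw_labels == c)]
        member_widths = [widths.get(n, np.nan) for n in members]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_w = float(np.nanmean(member_widths)) if member_widths else np.nan
        stats.append((c, mean_w, len(members)))
    stats.sort(key=lambda t: (-(t[1] if np.isfinite(t[1]) else -np.inf), -t[2], t[0]))
    relabel = {c: i + 1 for i, (c, _, _) in enumerate(stats)}
    labels = {n: relabel[raw_labels[i]] for i, n in enumerate(names)}
    centroids = pd.DataFrame(
        {relabel[c]: km.cluster_centers_[c] for c, _, _ in stats}
    ).T.sort_index()
    centroids.columns = matrix.data.columns
    class_mean_width = {relabel[c]: w for c, w, _ in stats}
    return ClassAssignment(labels, centroids, class_mean_width)


def class_timing_composition(
    assignment: ClassAssignment, origins: list[OriginRecord]
) -> pd.DataFrame:
    """Per-timing-group class fractions.

    Rows are timing groups (early/late), columns class ids; each row
    sums to 1 over the group's classified origins.
    """
    timing = {o.name: o.timing for o in origins}
    rows = {}
    for group in ("early", "late"):
        members = [
            n for n, t in timing.items() if t == group and n in assignment.labels
        ]
        if not members:
            continue
        counts = pd.Series([assignment.labels[n] for n in members]).value_counts()
        fractions = counts.reindex(range(1, assignment.k + 1), fill_value=0) / len(members)
        rows[group] = fractions
    if not rows:
        raise ValueError("no origins carry early/late timing labels")
    return pd.DataFrame(rows).T
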