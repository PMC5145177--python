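"""Connectivity statistics derived from settlement events.

Everything downstream of the particle tracker lives here: settlement
matrices at pixel and island resolution, forward/rearward probability
matrices, self-recruitment, the source–sink index, dispersal-distance
summaries (including the product-matrix island means), settlement time
series, seasonal subsets, matrix differencing and permutation Mantel
comparisons, plus the CSV/heatmap export dialects.

Orientation conventions
-----------------------
Settlement matrices S[i, j] count particles released at source site i that
settled at receiving site j.  The *rearward* probability matrix is
receiving-normalized: its row r gives the origin composition of settlers
arriving at island r (P = S_ij / sum_i S_ij), so each row with at least one
settler sums to exactly 1.  The *forward* matrix is source-normalized: row
s gives the destination composition of island s's successful particles.
Zero-settler (or zero-output) islands yield flagged all-zero rows, never
NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .habitat import HabitatGrid, pixel_distance_matrix
from .tracker import FATE_SETTLED, ReleaseSchedule, _validate_months


@dataclass
class SettlementMatrix:
    """Square count matrix S[source, receiving] with a resolution tag."""

    values: np.ndarray
    labels: list
    resolution: str  # "pixel" | "island"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("settlement matrix must be square")
        if np.any(self.values < 0):
            raise ValueError("settlement counts must be nonnegative")
        if self.resolution not in ("pixel", "island"):
            raise ValueError("resolution must be 'pixel' or 'island'")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class ProbabilityMatrix:
    """Probability matrix with a direction tag and zero-row flags.

    ``zero_rows[r]`` is True where the normalizing total for row r was zero;
    those rows are all-zero by convention.
    """

    values: np.ndarray
    labels: list
    direction: str  # "rearward" | "forward"
    zero_rows: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.direction not in ("rearward", "forward"):
            raise ValueError("direction must be 'rearward' or 'forward'")
        if self.zero_rows is None:
            self.zero_rows = np.zeros(self.values.shape[0], dtype=bool)
        else:
            self.zero_rows = np.asarray(self.zero_rows, dtype=bool)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


@dataclass
class DistanceSummary:
    """Summary of per-particle dispersal distances of settled particles."""

    mean_km: float
    median_km: float
    se_km: float
    n: int
    kde_grid_km: np.ndarray
    kde_density: np.ndarray


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def settlement_matrix(events: pd.DataFrame, grid: HabitatGrid, replicate=None) -> SettlementMatrix:
    """Pixel-resolution settlement counts from an events frame.

    Lost particles are excluded.  By default counts are pooled (summed)
    across replicates; pass ``replicate`` to select a single one, and use
    :func:`reefdrift.tracker.average_replicates` on per-replicate matrices
    for the replicate-averaged real-valued matrix.
    """
    ev = events[events["fate"] == FATE_SETTLED]
    if replicate is not None:
        ev = ev[ev["replicate"] == replicate]
    n = grid.n_pixels
    S = np.zeros((n, n))
    if len(ev):
        np.add.at(S, (ev["release_pixel"].to_numpy(int), ev["settle_pixel"].to_numpy(int)), 1.0)
    return SettlementMatrix(S, list(range(n)), "pixel")


def bin_by_island(S: SettlementMatrix, grid: HabitatGrid) -> SettlementMatrix:
    """Aggregate a pixel matrix to island resolution (grand total preserved)."""
    if S.resolution != "pixel":
        raise ValueError("bin_by_island expects a pixel-resolution matrix")
    if S.values.shape[0] != grid.n_pixels:
        raise ValueError("matrix size does not match habitat grid")
    idx = grid.island_index()
    k = grid.n_islands
    Z = np.zeros((grid.n_pixels, k))
    Z[np.arange(grid.n_pixels), idx] = 1.0
    return SettlementMatrix(Z.T @ S.values @ Z, grid.island_names, "island")


def _normalize(S_vals: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    totals = S_vals.sum(axis=axis)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    if axis == 0:  # column totals -> receiving-normalized, transpose to rows
        P = (S_vals / safe[None, :]).T
    else:
        P = S_vals / safe[:, None]
    P[zero, :] = 0.0
    return P, zero


def rearward_probability(S: SettlementMatrix) -> ProbabilityMatrix:
    """Receiving-normalized probabilities: row r = origin mix of settlers at r.

    P[r, i] = S[i, r] / sum_i' S[i', r].  Rows of islands with at least one
    settler sum to 1; zero-settler islands give flagged all-zero rows.
    """
    P, zero = _normalize(S.values, axis=0)
    return ProbabilityMatrix(P, S.labels, "rearward", zero)


def forward_probability(S: SettlementMatrix) -> ProbabilityMatrix:
    """Source-normalized probabilities: row s = destination mix of source s."""
    P, zero = _normalize(S.values, axis=1)
    return ProbabilityMatrix(P, S.labels, "forward", zero)


def matrix_difference(A: ProbabilityMatrix, B: ProbabilityMatrix) -> np.ndarray:
    """Elementwise A − B for same-direction probability matrices.

    Forward matrices are only comparable with forward matrices and rearward
    with rearward; a direction mismatch is a hard error.
    """
    if A.direction != B.direction:
        raise ValueError(f"direction mismatch: {A.direction} vs {B.direction}")
    if A.values.shape != B.values.shape:
        raise ValueError("shape mismatch")
    return A.values - B.values


def mantel_test(A, B, n_perm: int = 999, seed=None, include_diagonal: bool = False) -> MantelResult:
    """Permutation Mantel test between two square matrices.

    Pearson correlation over the off-diagonal cells (connectivity matrices
    are dominated by self-recruitment on the diagonal; set
    ``include_diagonal=True`` for the variant that keeps it).  The null is
    generated by simultaneous random permutation of B's row and column
    labels; the one-sided p-value is (count of permuted r >= observed r
    + 1) / (n_perm + 1).

    A constant input matrix makes r undefined; the result is then
    (nan, nan) rather than an exception.
    """
    Av = np.asarray(getattr(A, "values", A), dtype=float)
    Bv = np.asarray(getattr(B, "values", B), dtype=float)
    if Av.shape != Bv.shape or Av.ndim != 2 or Av.shape[0] != Av.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = Av.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites for a Mantel test")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    mask = np.ones((n, n), dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(mask, False)
    va = Av[mask]
    vb = Bv[mask]
    if np.std(va) == 0 or np.std(vb) == 0:
        return MantelResult(np.nan, np.nan, n_perm)

    za = (va - va.mean()) / va.std()

    def _r(vec):
        s = vec.std()
        if s == 0:
            return np.nan
        return float(np.mean(za * (vec - vec.mean()) / s))

    r_obs = _r(vb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_perm = _r(Bv[np.ix_(p, p)][mask])
        if np.isnan(r_perm):
            continue
        if r_perm >= r_obs:
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm)


# ---------------------------------------------------------------------------
# per-island metrics
# ---------------------------------------------------------------------------


def self_recruitment(S: SettlementMatrix) -> np.ndarray:
    """Per-island fraction of settlers that originated on the same island.

    SR[a] = S[a, a] / sum_i S[i, a].  Islands with zero settlers are
    reported as NaN (missing), not 0.
    """
    vals = S.values
    settlers = vals.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sr = np.diag(vals) / settlers
    return np.where(settlers > 0, sr, np.nan)


def source_sink_index(S: SettlementMatrix) -> np.ndarray:
    """(export − import) / (export + import) per island, in [−1, 1].

    Export E[a] counts all settled particles released from a (self-recruits
    included) and import I[a] all settlers arriving at a (self included),
    so the self term cancels in the numerator: an island whose only
    settlers are its own recruits scores exactly 0.  Islands with no flux
    at all also score 0 by convention.
    """
    vals = S.values
    E = vals.sum(axis=1)
    I = vals.sum(axis=0)
    tot = E + I
    with np.errstate(invalid="ignore", divide="ignore"):
        ssi = (E - I) / tot
    return np.where(tot > 0, ssi, 0.0)


def island_mean_dispersal_distance(S: SettlementMatrix, D: np.ndarray, grid: HabitatGrid) -> np.ndarray:
    """Mean settler dispersal distance (km) per receiving island.

    The pixel settlement matrix is multiplied elementwise with the pixel
    distance matrix to form a product matrix; both are binned by island and
    the column sums divided — i.e. a settler-weighted mean of source→sink
    pixel distances at each receiving island.  Zero-settler islands are NaN.
    """
    if S.resolution != "pixel":
        raise ValueError("island_mean_dispersal_distance expects a pixel matrix")
    D = np.asarray(D, dtype=float)
    if D.shape != S.values.shape:
        raise ValueError("distance matrix shape does not match settlement matrix")
    P = SettlementMatrix(S.values * D, S.labels, "pixel")
    PI = bin_by_island(P, grid).values
    SI = bin_by_island(S, grid).values
    settlers = SI.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_km = PI.sum(axis=0) / settlers
    return np.where(settlers > 0, mean_km, np.nan)


def dispersal_distance_summary(events: pd.DataFrame, n_grid: int = 256) -> DistanceSummary:
    """Mean/median/SE and a Gaussian KDE of settled-particle distances.

    The kernel-density estimate uses Silverman's bandwidth on a regular
    grid from 0 to 1.1 × max distance.  SE is sample sd / sqrt(n) (NaN for
    n = 1; the KDE is empty when the distances are degenerate).
    """
    d = events.loc[events["fate"] == FATE_SETTLED, "displacement_km"].to_numpy(dtype=float)
    if len(d) == 0:
        raise ValueError("no settled events")
    mean = float(np.mean(d))
    median = float(np.median(d))
    se = float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan
    grid_km = np.linspace(0.0, max(d.max(), 1e-9) * 1.1, n_grid)
    if len(d) > 1 and np.std(d) > 0:
        kde = stats.gaussian_kde(d, bw_method="silverman")
        dens = kde(grid_km)
    else:
        dens = np.full(n_grid, np.nan)
    return DistanceSummary(mean, median, se, len(d), grid_km, dens)


def settlement_time_series(events: pd.DataFrame, schedule: ReleaseSchedule) -> pd.DataFrame:
    """Per-release-date settlement fraction, attributed to the release cohort.

    Counts are pooled over replicates (the pooled ratio equals the
    replicate-mean fraction when cohort sizes are equal).  Returns a frame
    with columns release_date, released, settled, fraction.
    """
    by = events.groupby("release_date")
    released = by.size()
    settled = by.apply(lambda g: int((g["fate"] == FATE_SETTLED).sum()), include_groups=False)
    out = pd.DataFrame({"release_date": schedule.dates})
    out["released"] = released.reindex(schedule.dates).fillna(0).to_numpy(int)
    out["settled"] = settled.reindex(schedule.dates).fillna(0).to_numpy(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = out["settled"] / out["released"]
    out["fraction"] = frac.fillna(0.0)
    return out


def island_settlement_fraction(events: pd.DataFrame, grid: HabitatGrid, denominator: str = "archipelago") -> np.ndarray:
    """Fraction of released particles that settled at each island.

    ``denominator="archipelago"`` (default) divides each island's settler
    count by the total number of particles released anywhere over the
    period, so the island fractions sum to the overall settlement fraction.
    ``denominator="island"`` instead divides by the particles released from
    that island.
    """
    if denominator not in ("archipelago", "island"):
        raise ValueError("denominator must be 'archipelago' or 'island'")
    idx = grid.island_index()
    k = grid.n_islands
    settled = events[events["fate"] == FATE_SETTLED]
    arrivals = np.zeros(k)
    if len(settled):
        np.add.at(arrivals, idx[settled["settle_pixel"].to_numpy(int)], 1.0)
    if denominator == "archipelago":
        total = len(events)
        return arrivals / total if total else arrivals
    released = np.zeros(k)
    np.add.at(released, idx[events["release_pixel"].to_numpy(int)], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = arrivals / released
    return np.where(released > 0, frac, np.nan)


def filter_by_release_months(obj, months={5, 6}):
    """Restrict events (or a schedule) to releases in the given calendar months.

    The seasonal analyses are a post-hoc filter on one particle set; the
    default {5, 6} covers the May–June peak spawning season.  An empty
    month set is an error; a filter that matches nothing returns an empty
    subset (downstream metrics then report missing values).
    """
    months = _validate_months(months)
    if isinstance(obj, ReleaseSchedule):
        return obj.filter_months(months)
    dates = pd.DatetimeIndex(obj["release_date"])
    return obj[dates.month.isin(sorted(months))]


def connectivity_summary(events: pd.DataFrame, grid: HabitatGrid) -> pd.DataFrame:
    """Per-island summary table: SR, source–sink index, mean distance, settlement.

    Convenience wrapper bundling the island-level metrics into one frame in
    island (first-appearance) order.
    """
    S_pix = settlement_matrix(events, grid)
    S_isl = bin_by_island(S_pix, grid)
    D = pixel_distance_matrix(grid)
    return pd.DataFrame(
        {
            "island": grid.island_names,
            "self_recruitment": self_recruitment(S_isl),
            "source_sink_index": source_sink_index(S_isl),
            "mean_dispersal_km": island_mean_dispersal_distance(S_pix, D, grid),
            "settlement_fraction": island_settlement_fraction(events, grid),
        }
    )


# ---------------------------------------------------------------------------
# I/O and plotting
# ---------------------------------------------------------------------------


def write_matrix_csv(m, path) -> None:
    """Write a settlement or probability matrix with a tagged comment header."""
    if isinstance(m, SettlementMatrix):
        meta = f"# reefdrift-matrix kind=settlement resolution={m.resolution} rows=source cols=receiving"
    elif isinstance(m, ProbabilityMatrix):
        rows = "receiving" if m.direction == "rearward" else "source"
        meta = f"# reefdrift-matrix kind=probability direction={m.direction} rows={rows}"
    else:
        raise TypeError("expected SettlementMatrix or ProbabilityMatrix")
    df = pd.DataFrame(m.values, index=m.labels, columns=m.labels)
    with open(path, "w") as fh:
        fh.write(meta + "\n")
        df.to_csv(fh, index_label="label")


def read_matrix_csv(path):
    """Read a matrix written by :func:`write_matrix_csv` back into its type."""
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, index_col=0)
    tags = dict(tok.split("=", 1) for tok in header.lstrip("# ").split()[1:])
    labels = list(df.index)
    if tags.get("kind") == "settlement":
        return SettlementMatrix(df.to_numpy(dtype=float), labels, tags.get("resolution", "island"))
    if tags.get("kind") == "probability":
        vals = df.to_numpy(dtype=float)
        zero = vals.sum(axis=1) == 0
        return ProbabilityMatrix(vals, labels, tags.get("direction", "rearward"), zero)
    raise ValueError(f"unrecognized matrix header: {header!r}")


def plot_matrix(m, path=None, ax=None, cmap="viridis"):
    """Heatmap of a matrix with zero cells rendered white (no connectivity)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.asarray(getattr(m, "values", m), dtype=float)
    masked = np.ma.masked_where(vals == 0, vals)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    cm = matplotlib.colormaps[cmap].copy()
    cm.set_bad("white")
    im = ax.imshow(masked, cmap=cm, origin="upper")
    labels = getattr(m, "labels", None)
    if labels is not None and len(labels) <= 40:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
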