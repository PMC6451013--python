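"""Minimal species-distribution modelling: presence/background assembly,
surface-range-envelope (SRE) fitting, AUC/TSS evaluation on 75/25 splits,
TSS-gated ensembling, and projection onto substituted climate layers.

The SRE (climate envelope) declares a cell suitable iff every predictor
value falls inside the [q, 1-q] empirical quantile interval of the training
presences — the simplest presence-only SDM, but one whose evaluation and
ensembling machinery is shared by any score-producing algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geospatial import EARTH_RADIUS_KM

__all__ = [
    "RasterStack",
    "SdmEvaluation",
    "split_presences",
    "sre_fit",
    "sre_predict",
    "sre_fit_predict",
    "evaluate",
    "ensemble",
    "project",
]


@dataclass
class RasterStack:
    """Named 2-D layers on a shared lon/lat grid.

    ``transform`` is (x0, dx, y0, dy): cell (row, col) spans longitudes
    [x0 + col*dx, x0 + (col+1)*dx] and latitudes [y0 + row*dy,
    y0 + (row+1)*dy] (dy negative for a top-down grid).  NODATA is NaN and
    propagates across layers.
    """

    layers: dict[str, np.ndarray]
    transform: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers disagree on shape: {shapes}")
        (self.shape,) = shapes
        # NODATA in any layer masks the cell in all layers
        bad = np.zeros(self.shape, dtype=bool)
        for a in self.layers.values():
            bad |= np.isnan(a)
        for a in self.layers.values():
            a[bad] = np.nan
        self.nodata_mask = bad

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, dx, y0, dy = self.transform
        col = np.floor((np.asarray(lon) - x0) / dx).astype(int)
        row = np.floor((np.asarray(lat) - y0) / dy).astype(int)
        return row, col

    def values_at(self, coords: np.ndarray) -> dict[str, np.ndarray]:
        """Per-layer values at (lon, lat) points; out-of-grid -> NaN."""
        row, col = self.cell_of(coords[:, 0], coords[:, 1])
        nr, nc = self.shape
        ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        out = {}
        for name, a in self.layers.items():
            v = np.full(len(coords), np.nan)
            v[ok] = a[row[ok], col[ok]]
            out[name] = v
        return out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, dx, y0, dy = self.transform
        nr, nc = self.shape
        lon = x0 + (np.arange(nc) + 0.5) * dx
        lat = y0 + (np.arange(nr) + 0.5) * dy
        return lon, lat

    def cell_areas_km2(self) -> np.ndarray:
        """Per-cell spherical area in km^2 (constant per row)."""
        x0, dx, y0, dy = self.transform
        nr, nc = self.shape
        lat_edges = y0 + np.arange(nr + 1) * dy
        band = np.abs(np.sin(np.radians(lat_edges[1:]))
                      - np.sin(np.radians(lat_edges[:-1])))
        row_area = EARTH_RADIUS_KM ** 2 * np.radians(abs(dx)) * band
        return np.repeat(row_area[:, None], nc, axis=1)


@dataclass
class SdmEvaluation:
    """Evaluation of one model replicate."""

    auc: float
    tss: float
    threshold: float
    weight: float = field(default=0.0)


def split_presences(points: np.ndarray, stack: RasterStack,
                    background_n: int | None = None,
                    train_frac: float = 0.75, runs: int = 5,
                    seed: int = 0) -> list[dict]:
    """Replicated random train/test splits of presences plus background.

    Presences split floor(train_frac * n) train / rest test.  Background
    points are drawn uniformly from valid (non-NODATA) cells excluding
    cells holding a presence, then split with the same fraction.  Each run
    uses an independent RNG substream of ``seed``.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 4:
        raise ValueError("need at least 4 presence points")
    n_train = int(np.floor(train_frac * n))
    if n_train < 2 or n_train >= n:
        raise ValueError(f"train_frac={train_frac} leaves an empty split")
    if background_n is None:
        background_n = 10 * n
    if background_n < n:
        raise ValueError("background_n must be at least the presence count")
    prow, pcol = stack.cell_of(points[:, 0], points[:, 1])
    presence_cells = set(zip(prow.tolist(), pcol.tolist()))
    valid = np.argwhere(~stack.nodata_mask)
    valid = np.array([rc for rc in valid if tuple(rc) not in presence_cells])
    if len(valid) < background_n:
        raise ValueError("not enough valid background cells")
    lon, lat = stack.cell_centers()
    seeds = np.random.SeedSequence(seed).spawn(runs)
    out = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        bsel = valid[rng.choice(len(valid), size=background_n, replace=False)]
        bg = np.column_stack([lon[bsel[:, 1]], lat[bsel[:, 0]]])
        nb_train = int(np.floor(train_frac * background_n))
        bperm = rng.permutation(background_n)
        out.append({
            "train_presence": points[perm[:n_train]],
            "test_presence": points[perm[n_train:]],
            "train_background": bg[bperm[:nb_train]],
            "test_background": bg[bperm[nb_train:]],
        })
    return out


def sre_fit(train_presences: np.ndarray, stack: RasterStack,
            q: float = 0.025) -> dict[str, tuple[float, float]]:
    """Fit the surface-range envelope: per-layer [q, 1-q] presence quantiles
    (linear-interpolation convention)."""
    if not 0 <= q < 0.5:
        raise ValueError("q must be in [0, 0.5)")
    train_presences = np.asarray(train_presences, dtype=float)
    if len(train_presences) < 2:
        raise ValueError("need at least 2 training presences")
    vals = stack.values_at(train_presences)
    envelope = {}
    for name, v in vals.items():
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValueError(f"no presence values on layer {name!r}")
        envelope[name] = (float(np.quantile(v, q)),
                          float(np.quantile(v, 1.0 - q)))
    return envelope


def sre_predict(envelope: dict[str, tuple[float, float]],
                stack: RasterStack) -> np.ndarray:
    """Apply an envelope: 1.0 where every layer is inside its interval,
    0.0 outside, NaN at NODATA."""
    missing = [n for n in envelope if n not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks layer(s): {missing}")
    ok = np.ones(stack.shape, dtype=bool)
    for name, (lo, hi) in envelope.items():
        a = stack.layers[name]
        ok &= (a >= lo) & (a <= hi)
    out = ok.astype(float)
    out[stack.nodata_mask] = np.nan
    return out


def sre_fit_predict(train_presences: np.ndarray, stack: RasterStack,
                    q: float = 0.025) -> tuple[np.ndarray, dict]:
    """Fit the SRE on training presences and predict over the stack."""
    envelope = sre_fit(train_presences, stack, q)
    return sre_predict(envelope, stack), envelope


def evaluate(presence_scores: np.ndarray,
             background_scores: np.ndarray) -> SdmEvaluation:
    """AUC (rank formula with tie correction) and TSS (max over thresholds).

    TSS = max_t [sensitivity(t) + specificity(t) - 1] with suitability
    declared at score >= t.  All-identical scores give AUC 0.5 and TSS 0.
    """
    from scipy.stats import rankdata

    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need at least 1 test presence and 1 background")
    ranks = rankdata(np.concatenate([p, b]))
    auc = (ranks[: p.size].sum() - p.size * (p.size + 1) / 2) / (p.size * b.size)
    best_tss, best_thr = 0.0, float(np.min(np.concatenate([p, b])))
    for t in np.unique(np.concatenate([p, b])):
        sens = float((p >= t).mean())
        spec = float((b < t).mean())
        tss = sens + spec - 1.0
        if tss > best_tss:
            best_tss, best_thr = tss, float(t)
    return SdmEvaluation(auc=float(auc), tss=best_tss, threshold=best_thr)


def ensemble(predictions: list[np.ndarray], evaluations: list[SdmEvaluation],
             tss_min: float = 0.7) -> np.ndarray:
    """TSS-weighted consensus of the replicate predictions.

    Replicates with TSS <= ``tss_min`` get weight 0; remaining weights are
    the TSS values renormalised to sum to 1.
    """
    weights = np.array([e.tss if e.tss > tss_min else 0.0
                        for e in evaluations])
    for e, w in zip(evaluations, weights):
        e.weight = float(w)
    if weights.sum() <= 0:
        raise ValueError(
            f"no replicate exceeds TSS {tss_min}; relax the threshold")
    weights = weights / weights.sum()
    out = np.zeros_like(predictions[0], dtype=float)
    for pred, w in zip(predictions, weights):
        if w:
            out += w * pred
    return out


def project(envelope: dict[str, tuple[float, float]],
            current_stack: RasterStack, future_stack: RasterStack) -> dict:
    """Project an envelope onto substituted layers and summarise the change.

    Returns current/future suitability rasters plus suitable area (km^2)
    under each and the percent change.
    """
    cur = sre_predict(envelope, current_stack)
    fut = sre_predict(envelope, future_stack)
    areas_c = current_stack.cell_areas_km2()
    areas_f = future_stack.cell_areas_km2()
    a_cur = float(np.nansum(cur * areas_c))
    a_fut = float(np.nansum(fut * areas_f))
    pct = 100.0 * (a_fut - a_cur) / a_cur if a_cur > 0 else float("nan")
    return {"current": cur, "future": fut, "area_current_km2": a_cur,
            "area_future_km2": a_fut, "pct_change": pct}
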