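"""Static map rendering of presence/movement summary networks.

Stations are drawn at their WGS84 coordinates as circles sized and colored
by presence amount (small yellow = little time, large red = much time);
movement paths are straight lines under the nodes, width and color scaled by
path use.  Black dots always mark the station locations themselves.  No
basemap tiles are fetched — rendering is fully offline; a user-supplied
background image with geographic bounds can be placed under the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import LoggerIndex


@dataclass
class MapStyle:
    """Display scaling for :func:`render_summary_map`.

    Node sizes are matplotlib scatter areas (points^2), edge widths points.
    ``p_scale``/``m_scale`` are multiplicative tweaks applied after the
    linear scaling; the color ramp runs yellow (low) to red (high).
    """

    node_size: tuple[float, float] = (60.0, 900.0)
    edge_width: tuple[float, float] = (1.0, 8.0)
    colors: tuple[str, str] = ("#ffe066", "#c1272d")
    p_scale: float = 1.0
    m_scale: float = 1.0
    p_title: str = "Total time (min)"
    m_title: str = "Path use"
    station_marker_size: float = 12.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("node_size", self.node_size), ("edge_width", self.edge_width)):
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ValidationError(f"{name} range must be positive with min <= max: {(lo, hi)}")

    def colormap(self):
        from matplotlib.colors import LinearSegmentedColormap

        return LinearSegmentedColormap.from_list("perchflow", list(self.colors))


def scale_to_style(values, rng: tuple[float, float]) -> np.ndarray:
    """Linearly map non-negative amounts onto a display range.

    ``[min(values), max(values)]`` maps onto ``[lo, hi]``; constant inputs
    map to the midpoint so a single-valued layer still renders visibly.
    """
    vals = np.asarray(values, dtype=float)
    if (vals < 0).any():
        raise ValidationError("display scaling requires non-negative values")
    lo, hi = rng
    if vals.size == 0:
        return vals
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        return np.full(vals.shape, (lo + hi) / 2.0)
    return lo + (vals - vmin) / (vmax - vmin) * (hi - lo)


def _normalize(vals: np.ndarray) -> np.ndarray:
    if vals.size == 0:
        return vals
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        return np.full(vals.shape, 0.5)
    return (vals - vmin) / (vmax - vmin)


def _edge_coords(ms: pd.DataFrame, node_coords: dict[str, tuple[float, float]],
                 index: LoggerIndex | None):
    coords = dict(node_coords)
    if index is not None:
        for k, v in index.coords().items():
            coords.setdefault(k, v)
    missing: set[str] = set()
    segments = []
    for rec in ms.itertuples(index=False):
        seg = []
        for side in ("logger_1", "logger_2"):
            logger = str(getattr(rec, side))
            latlon = None
            if hasattr(rec, f"lat{side[-2:]}"):
                la = getattr(rec, f"lat{side[-2:]}")
                lo = getattr(rec, f"lon{side[-2:]}")
                if pd.notna(la) and pd.notna(lo):
                    latlon = (la, lo)
            if latlon is None:
                latlon = coords.get(logger)
            if latlon is None or any(pd.isna(x) for x in latlon):
                missing.add(logger)
            else:
                seg.append(latlon)
        segments.append(seg)
    if missing:
        raise ValidationError(f"missing coordinates for logger(s): {sorted(missing)}")
    return segments


def render_summary_map(
    ps: pd.DataFrame | None,
    ms: pd.DataFrame | None = None,
    style: MapStyle | None = None,
    out=None,
    index: LoggerIndex | None = None,
    allow_empty_movements: bool = False,
    ax=None,
):
    """Render presence/movement summaries to a static map.

    Parameters
    ----------
    ps, ms
        Presence summary (``logger_id``, ``lat``, ``lon``, ``amount``) and
        movement summary (``move_path``/``logger_1``/``logger_2``,
        ``path_use``).  ``ms`` may be empty only under
        ``allow_empty_movements``.
    out
        Optional image path; the figure is returned either way.
    index
        Fallback source of station coordinates for edge endpoints absent
        from ``ps``.
    """
    import matplotlib.pyplot as plt

    style = style or MapStyle()
    ps = ps if ps is not None else pd.DataFrame(columns=["logger_id", "lat", "lon", "amount"])
    ms = ms if ms is not None else pd.DataFrame(columns=["logger_1", "logger_2", "path_use"])
    if not len(ps) and not len(ms):
        raise ValidationError("nothing to draw: both summaries are empty")
    if not len(ms) and not allow_empty_movements:
        raise ValidationError("movement summary is empty (pass allow_empty_movements=True)")

    for c in ("logger_id", "lat", "lon", "amount"):
        if len(ps) and c not in ps.columns:
            raise ValidationError(f"presence summary missing column {c!r}")
    bad = ps[ps[["lat", "lon"]].isna().any(axis=1)] if len(ps) else ps
    if len(bad):
        raise ValidationError(
            f"missing coordinates for logger(s): {sorted(set(bad['logger_id'].astype(str)))}"
        )
    if len(ms):
        if "logger_1" not in ms.columns and "move_path" in ms.columns:
            split = ms["move_path"].astype(str).str.rsplit("_", n=1, expand=True)
            ms = ms.assign(logger_1=split[0], logger_2=split[1])
        for c in ("logger_1", "logger_2", "path_use"):
            if c not in ms.columns:
                raise ValidationError(f"movement summary missing column {c!r}")

    node_coords = {
        str(r.logger_id): (r.lat, r.lon) for r in ps.itertuples(index=False)
    } if len(ps) else {}

    cmap = style.colormap()
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 7))
    else:
        fig = ax.figure

    # edges under nodes
    if len(ms):
        segments = _edge_coords(ms, node_coords, index)
        widths = scale_to_style(ms["path_use"].to_numpy(), style.edge_width) * style.m_scale
        colors = cmap(_normalize(ms["path_use"].to_numpy(dtype=float)))
        for seg, w, col in zip(segments, widths, colors):
            (la1, lo1), (la2, lo2) = seg
            ax.plot([lo1, lo2], [la1, la2], "-", linewidth=w, color=col,
                    solid_capstyle="round", zorder=1)

    if len(ps):
        sizes = scale_to_style(ps["amount"].to_numpy(), style.node_size) * style.p_scale
        colors = cmap(_normalize(ps["amount"].to_numpy(dtype=float)))
        ax.scatter(ps["lon"], ps["lat"], s=sizes, c=colors, edgecolors="black",
                   linewidths=0.5, zorder=2, label="_presence")

    # station locations always drawn on top
    all_coords = dict(node_coords)
    if index is not None:
        for k, v in index.coords().items():
            all_coords.setdefault(k, v)
    if all_coords:
        lats, lons = zip(*all_coords.values())
        ax.scatter(lons, lats, s=style.station_marker_size, c="black", zorder=3,
                   label="_stations")

    _add_legends(ax, ps, ms, style, cmap)
    ax.set_xlabel("Longitude")
    ax.set_ylabel("Latitude")
    ax.set_aspect("equal", adjustable="datalim")
    if out is not None:
        fig.savefig(out, dpi=150, bbox_inches="tight")
    return fig


def _legend_values(vals: np.ndarray) -> np.ndarray:
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        return np.array([vmin])
    return np.array([vmin, (vmin + vmax) / 2.0, vmax])


def _add_legends(ax, ps, ms, style, cmap) -> None:
    from matplotlib.lines import Line2D

    legends = []
    if len(ps):
        vals = _legend_values(ps["amount"].to_numpy(dtype=float))
        sizes = scale_to_style(vals, style.node_size) * style.p_scale
        handles = [
            Line2D([], [], marker="o", linestyle="", markersize=np.sqrt(s),
                   markerfacecolor=cmap(q), markeredgecolor="black",
                   label=f"{v:g}")
            for v, s, q in zip(vals, sizes, _normalize(vals))
        ]
        legends.append((handles, style.p_title, "upper left"))
    if len(ms):
        vals = _legend_values(ms["path_use"].to_numpy(dtype=float))
        widths = scale_to_style(vals, style.edge_width) * style.m_scale
        handles = [
            Line2D([], [], linestyle="-", linewidth=w, color=cmap(q), label=f"{v:g}")
            for v, w, q in zip(vals, widths, _normalize(vals))
        ]
        legends.append((handles, style.m_title, "lower left"))
    first = None
    for handles, title, loc in legends:
        leg = ax.legend(handles=handles, title=title, loc=loc, fontsize=8, title_fontsize=9)
        if first is None:
            first = leg
        else:
            ax.add_artist(first)
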