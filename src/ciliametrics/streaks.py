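"""Swimming-trajectory recognition in long-exposure streak micrographs.

At a 1-s exposure each swimming cell draws a bright streak whose geometry
encodes its motion: the contour length of the path divided by the exposure
gives the actual swimming velocity, and the end-to-end distance gives the
linear velocity. The pipeline is threshold → connected components →
skeletonize → prune spurs → weighted path length (orthogonal steps 1 px,
diagonal steps √2 px). Components that touch the frame border, have more
than two skeleton endpoints after pruning (crossing tracks), or fall outside
the contour-length window are flagged and excluded from summaries by
default rather than being split or repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize, remove_small_objects

from .calibration import ImageCalibration

__all__ = [
    "StreakTrack",
    "TrackFilterParams",
    "to_8bit",
    "binarize",
    "extract_tracks",
    "annotate_overlay",
    "summarize_velocities",
    "skeleton_path_length_px",
]

SQRT2 = math.sqrt(2.0)

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class TrackFilterParams:
    """Explicit, reproducible replacement for manual false-track deletion."""

    min_contour_um: float = 20.0
    max_contour_um: float = 500.0
    border_margin_px: int = 2
    max_endpoints: int = 2
    threshold_method: str = "otsu"  # "otsu" or "fixed"
    fixed_threshold: float = 128.0
    min_object_px: int = 10
    spur_prune_px: int = 5
    smooth_px: float = 1.5  # pre-threshold Gaussian; 0 disables

    def validate(self) -> None:
        if not (self.min_contour_um < self.max_contour_um):
            raise ValueError("min_contour_um must be < max_contour_um")
        if self.border_margin_px < 0 or self.min_object_px < 0 or self.spur_prune_px < 0:
            raise ValueError("margins and floors must be non-negative")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


@dataclass
class StreakTrack:
    """One recognized swimming trajectory."""

    track_id: int
    n_px: int
    contour_length_um: float
    end_to_end_um: float
    velocity_actual_um_s: float
    velocity_linear_um_s: float
    straightness: float
    touches_border: bool = False
    branched: bool = False
    below_min_length: bool = False
    above_max_length: bool = False
    bbox: tuple[int, int, int, int] = field(default=(0, 0, 0, 0), repr=False)
    skeleton_rc: np.ndarray | None = field(default=None, repr=False)

    @property
    def flagged(self) -> bool:
        return self.touches_border or self.branched or self.below_min_length or self.above_max_length

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k not in ("bbox", "skeleton_rc")}
        d["flagged"] = self.flagged
        return d


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Linear min–max rescale of a 2-D grayscale image to uint8 [0, 255].

    Constant images map to all zeros. Midpoints round half-to-even
    (``np.rint``), so {100, 200, 300} maps to {0, 128, 255}.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    img = image.astype(float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(image.shape, np.uint8)
    return np.rint((img - lo) / (hi - lo) * 255.0).astype(np.uint8)


def binarize(image: np.ndarray, params: TrackFilterParams | None = None) -> np.ndarray:
    """Threshold an 8-bit streak image into a foreground mask.

    A mild Gaussian blur (``smooth_px``) is applied first so shot noise on
    the streak edges does not serrate the mask — a ragged ribbon boundary
    makes the subsequent skeleton wiggle and inflates path lengths. Otsu
    thresholding by default (fixed threshold available); objects smaller
    than ``min_object_px`` are removed. An empty mask is a valid result.
    """
    from scipy.ndimage import gaussian_filter

    params = params or TrackFilterParams()
    params.validate()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    work = gaussian_filter(image.astype(float), params.smooth_px) \
        if params.smooth_px > 0 else image
    if params.threshold_method == "otsu":
        if image.min() == image.max():
            return np.zeros(image.shape, bool)
        thr = threshold_otsu(work)
    else:
        thr = params.fixed_threshold
    mask = work > thr
    if params.min_object_px > 1:
        # removes objects of up to max_size pixels, i.e. strictly smaller
        # than min_object_px
        mask = remove_small_objects(mask, max_size=params.min_object_px - 1)
    return mask


# ---------------------------------------------------------------------------
# skeleton geometry
# ---------------------------------------------------------------------------

def _skeleton_adjacency(coords: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    pix = set(map(tuple, coords))
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pix}
    for p in pix:
        for dr, dc in _NEIGHBORS:
            q = (p[0] + dr, p[1] + dc)
            if q in pix:
                adj[p].append(q)
    return adj


def _endpoints(adj: dict) -> list[tuple[int, int]]:
    return [p for p, nbrs in adj.items() if len(nbrs) <= 1]


def _prune_spurs(adj: dict, max_len_px: int) -> dict:
    """Iteratively delete terminal branches shorter than ``max_len_px`` pixels.

    A spur is walked from its endpoint to the first junction (pixel with >2
    neighbours); if the walk is shorter than the prune length, its pixels are
    removed. Repeats until stable so stubble left by thinning disappears
    while genuine track ends survive.
    """
    if max_len_px <= 0:
        return adj
    changed = True
    while changed:
        changed = False
        for ep in _endpoints(adj):
            if ep not in adj:
                continue
            path = [ep]
            prev, cur = None, ep
            while len(path) <= max_len_px:
                nbrs = [q for q in adj[cur] if q != prev]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                if len(adj[nxt]) > 2:  # reached a junction: path is a spur
                    if len(path) < max_len_px:
                        for p in path:
                            for q in adj[p]:
                                adj[q] = [r for r in adj[q] if r != p]
                            del adj[p]
                        changed = True
                    break
                path.append(nxt)
                prev, cur = cur, nxt
    return adj


def _dijkstra_farthest(adj: dict, start: tuple[int, int]) -> tuple[tuple[int, int], float, dict]:
    """Weighted BFS/Dijkstra over skeleton pixels (1 / √2 step weights)."""
    import heapq

    dist = {start: 0.0}
    heap = [(0.0, start)]
    far, far_d = start, 0.0
    while heap:
        d, p = heapq.heappop(heap)
        if d > dist.get(p, math.inf):
            continue
        if d > far_d:
            far, far_d = p, d
        for q in adj[p]:
            w = SQRT2 if (p[0] != q[0] and p[1] != q[1]) else 1.0
            nd = d + w
            if nd < dist.get(q, math.inf):
                dist[q] = nd
                heapq.heappush(heap, (nd, q))
    return far, far_d, dist


def skeleton_path_length_px(coords: np.ndarray) -> tuple[float, tuple, tuple, int]:
    """Longest weighted shortest path across a skeleton's pixel set.

    Returns (length in pixel units, endpoint A, endpoint B, n_endpoints).
    Orthogonal steps count 1, diagonal steps √2. For a simple 2-endpoint
    skeleton this is exactly the path between its endpoints; for branched
    skeletons it is the weighted diameter measured from the endpoint set.
    """
    adj = _skeleton_adjacency(coords)
    if not adj:
        return 0.0, (0, 0), (0, 0), 0
    eps = _endpoints(adj)
    n_ep = len(eps)
    if n_ep == 0:  # closed loop: start anywhere
        eps = [next(iter(adj))]
    # double sweep: farthest point from an endpoint, then farthest from that
    a, _, _ = _dijkstra_farthest(adj, eps[0])
    best_len, best_pair = 0.0, (a, a)
    for ep in (eps if n_ep > 0 else [a]):
        far, d, _ = _dijkstra_farthest(adj, ep)
        if d > best_len:
            best_len, best_pair = d, (ep, far)
    return best_len, best_pair[0], best_pair[1], n_ep


def extract_tracks(
    mask: np.ndarray,
    cal: ImageCalibration,
    params: TrackFilterParams | None = None,
) -> list[StreakTrack]:
    """Measure every connected component of a streak mask.

    Components are 8-connected, skeletonized by topology-preserving thinning,
    spur-pruned, and measured as the weighted skeleton path (orthogonal 1 px,
    diagonal √2 px) scaled by ``um_per_px``. Tracks are numbered in raster
    order of their bounding-box top-left corner, starting at 1.
    """
    params = params or TrackFilterParams()
    params.validate()
    exposure = cal.require_exposure()
    mask = np.asarray(mask).astype(bool)
    labels = label(mask, connectivity=2)
    regions = sorted(regionprops(labels), key=lambda r: (r.bbox[0], r.bbox[1]))

    h, w = mask.shape
    m = params.border_margin_px
    tracks: list[StreakTrack] = []
    for i, reg in enumerate(regions, start=1):
        comp = labels[reg.bbox[0]:reg.bbox[2], reg.bbox[1]:reg.bbox[3]] == reg.label
        skel = skeletonize(comp)
        coords = np.argwhere(skel)
        adj = _skeleton_adjacency(coords)
        adj = _prune_spurs(adj, params.spur_prune_px)
        if not adj:
            continue
        pruned = np.array(sorted(adj.keys()))
        length_px, ep_a, ep_b, n_ep = skeleton_path_length_px(pruned)
        contour_um = length_px * cal.um_per_px
        e2e_um = math.hypot(ep_a[0] - ep_b[0], ep_a[1] - ep_b[1]) * cal.um_per_px
        straight = e2e_um / contour_um if contour_um > 0 else 1.0

        r0, c0, r1, c1 = reg.bbox
        tracks.append(StreakTrack(
            track_id=i,
            n_px=len(adj),
            contour_length_um=contour_um,
            end_to_end_um=e2e_um,
            velocity_actual_um_s=contour_um / exposure,
            velocity_linear_um_s=e2e_um / exposure,
            straightness=straight,
            touches_border=(r0 <= m or c0 <= m or r1 >= h - m or c1 >= w - m),
            branched=(n_ep > params.max_endpoints),
            below_min_length=(contour_um < params.min_contour_um),
            above_max_length=(contour_um > params.max_contour_um),
            bbox=reg.bbox,
            skeleton_rc=pruned + np.array([r0, c0]),
        ))
    return tracks


def annotate_overlay(image: np.ndarray, tracks: list[StreakTrack]) -> np.ndarray:
    """RGB overlay: retained tracks outlined in green with their id rendered
    nearby, flagged tracks in red. Returns a copy; an empty track list gives
    an unmodified (grayscale→RGB) copy of the input.
    """
    from PIL import Image, ImageDraw

    base = to_8bit(image) if image.dtype != np.uint8 else image
    rgb = Image.fromarray(np.stack([base] * 3, axis=-1))
    draw = ImageDraw.Draw(rgb)
    for tr in tracks:
        r0, c0, r1, c1 = tr.bbox
        color = (255, 64, 64) if tr.flagged else (64, 255, 64)
        draw.rectangle([c0 - 1, r0 - 1, c1, r1], outline=color)
        draw.text((c0 + 2, max(r0 - 12, 0)), str(tr.track_id), fill=color)
    return np.asarray(rgb)


def summarize_velocities(
    tracks: list[StreakTrack], exclude_flagged: bool = True
) -> dict:
    """Per-image summary (n, mean, sd with n−1 denominator) of the actual
    velocity over retained tracks. Empty input gives n=0 and NaN moments."""
    kept = [t for t in tracks if not (exclude_flagged and t.flagged)]
    v = np.array([t.velocity_actual_um_s for t in kept], float)
    return {
        "n": int(v.size),
        "mean_velocity_um_s": float(v.mean()) if v.size else float("nan"),
        "sd_velocity_um_s": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
    }


def match_tracks_to_truth(
    tracks: list[StreakTrack],
    truth: pd.DataFrame,
    cal: ImageCalibration,
    max_dist_um: float = 15.0,
) -> pd.DataFrame:
    """Greedily pair measured tracks with ground-truth cells by endpoints.

    For each unflagged track, the candidate cell minimizes the summed
    distance between the track's skeleton endpoints and the cell's true
    path endpoints (either orientation); pairs farther than ``max_dist_um``
    per endpoint on average are left unmatched. Returns one row per matched
    pair with measured and true velocities, for recovery analysis free of
    border/crossing selection effects.
    """
    rows = []
    taken: set[int] = set()
    for tr in tracks:
        if tr.flagged or tr.skeleton_rc is None or len(tr.skeleton_rc) < 2:
            continue
        # endpoints of the measured path in µm (x = col, y = row)
        adj = _skeleton_adjacency(tr.skeleton_rc)
        _, ep_a, ep_b, _ = skeleton_path_length_px(tr.skeleton_rc)
        ax, ay = ep_a[1] * cal.um_per_px, ep_a[0] * cal.um_per_px
        bx, by = ep_b[1] * cal.um_per_px, ep_b[0] * cal.um_per_px
        best = (math.inf, None)
        for _, cell in truth.iterrows():
            if int(cell["cell_id"]) in taken:
                continue
            d1 = (math.hypot(ax - cell["x_start_um"], ay - cell["y_start_um"])
                  + math.hypot(bx - cell["x_end_um"], by - cell["y_end_um"]))
            d2 = (math.hypot(bx - cell["x_start_um"], by - cell["y_start_um"])
                  + math.hypot(ax - cell["x_end_um"], ay - cell["y_end_um"]))
            d = min(d1, d2) / 2.0
            if d < best[0]:
                best = (d, cell)
        if best[1] is not None and best[0] <= max_dist_um:
            cell = best[1]
            taken.add(int(cell["cell_id"]))
            rows.append({
                "track_id": tr.track_id,
                "cell_id": int(cell["cell_id"]),
                "match_dist_um": best[0],
                "velocity_actual_um_s": tr.velocity_actual_um_s,
                "true_speed_um_s": cell["mean_speed_um_s"],
            })
    return pd.DataFrame(rows)


def tracks_to_frame(tracks: list[StreakTrack]) -> pd.DataFrame:
    """Tidy one-row-per-track table of all StreakTrack fields."""
    if not tracks:
        return pd.DataFrame(columns=[
            "track_id", "n_px", "contour_length_um", "end_to_end_um",
            "velocity_actual_um_s", "velocity_linear_um_s", "straightness",
            "touches_border", "branched", "below_min_length", "above_max_length",
            "flagged",
        ])
    return pd.DataFrame([t.to_dict() for t in tracks])
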