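"""Procedural vascular networks with exact ground truth.

The generator grows branching capillary trees inside a rectangular skin
patch, renders them into en-face angiography images for the three
perfusion states of a reactive-hyperemia protocol (baseline, compressed,
hyperemia), injects the two dominant OCT-A artifact classes
(multiplicative speckle and additive stripes along the fast scan axis),
and renders serial histology sections with known inter-section jitter and
tissue shrinkage.

Ground truth is analytic: segment geometry lives in micrometer
coordinates, centerline length is the Euclidean sum over perfused
segments, branch points are graph nodes of degree >= 3, and the truth
area fraction is measured on the same rasterization the images use, so a
segmentation algorithm is judged against an achievable target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .images import EnFaceImage, HistologyStack


class DensityUnreachableError(RuntimeError):
    """Raised when the requested vessel density cannot be grown."""


@dataclass(frozen=True)
class Segment:
    """One straight vessel segment in micrometer coordinates."""

    start_um: tuple[float, float]  # (x, y)
    end_um: tuple[float, float]
    diameter_um: float
    perfused_baseline: bool
    nodes: tuple[int, int]  # graph node ids of (start, end)

    @property
    def length_um(self) -> float:
        dx = self.end_um[0] - self.start_um[0]
        dy = self.end_um[1] - self.start_um[1]
        return float(np.hypot(dx, dy))


@dataclass(frozen=True)
class TruthMetrics:
    """Analytic metric triple for one perfusion state."""

    area_fraction: float  # dimensionless (rasterized vessel pixels / all)
    centerline_length_per_area: float  # mm of centerline per mm^2
    branch_count: int


@dataclass
class BranchingParams:
    """Growth rules for the rejection-sampled branching tree.

    Diameters default to 15-65 um, bracketing the 22-32 um mean capillary
    diameters typical of the upper dermal plexus; segment lengths are a
    few hundred micrometers so inter-junction spacing is well above the
    pixel scale.
    """

    n_seed_trees: int = 4
    segment_length_um: tuple[float, float] = (120.0, 300.0)
    trunk_diameter_um: tuple[float, float] = (40.0, 60.0)
    diameter_decay: tuple[float, float] = (0.82, 0.96)
    min_diameter_um: float = 15.0
    max_diameter_um: float = 65.0
    cone_half_angle_deg: float = 70.0
    bifurcation_prob: float = 0.6
    unperfused_terminal_frac: float = 0.6
    clearance_um: float = 39.0  # min gap between unrelated vessel walls
    max_segments: Optional[int] = None  # explicit cap; disables density errors


@dataclass
class ArtifactParams:
    """Parameters of the injected OCT-A artifacts.

    speckle_contrast is the coefficient of variation of the multiplicative
    gamma speckle (0 disables it); stripe_amplitude is the peak additive
    stripe offset as a fraction of the [0, 1] dynamic range.
    """

    speckle_contrast: float = 0.5
    stripe_amplitude: float = 0.15
    stripe_axis: str = "fast"
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_contrast < 0:
            raise ValueError("speckle_contrast must be >= 0")
        if not 0.0 <= self.stripe_amplitude <= 1.0:
            raise ValueError("stripe_amplitude must be in [0, 1]")
        if self.stripe_axis not in ("fast", "slow"):
            raise ValueError("stripe_axis must be 'fast' or 'slow'")


@dataclass
class NetworkTruth:
    """A generated vascular network plus its analytic metrics."""

    segments: list[Segment]
    field_size_um: tuple[float, float]  # (width x, height y)
    truth_metrics: dict[str, TruthMetrics] = field(default_factory=dict)
    raster_pitch_um: float = 6.5
    seed: int = 0

    # -- analytic bookkeeping ------------------------------------------------

    def _selected(self, state: str) -> list[Segment]:
        if state == "compressed":
            return []
        if state == "baseline":
            return [s for s in self.segments if s.perfused_baseline]
        if state in ("hyperemia", "histology"):
            return list(self.segments)
        raise ValueError(f"unknown state {state!r}")

    def centerline_length_um(self, state: str) -> float:
        """Euclidean centerline length summed over the state's segments."""
        return float(sum(s.length_um for s in self._selected(state)))

    def branch_count(self, state: str) -> int:
        """Graph nodes of degree >= 3 within the state's perfused subgraph."""
        g = nx.MultiGraph()
        for s in self._selected(state):
            g.add_edge(*s.nodes)
        return int(sum(1 for _, d in g.degree() if d >= 3))

    @property
    def field_area_mm2(self) -> float:
        return self.field_size_um[0] * self.field_size_um[1] / 1e6

    def compute_truth(
        self, state: str, dilation_factor: float = 1.0, pixel_pitch_um: Optional[float] = None
    ) -> TruthMetrics:
        pitch = self.raster_pitch_um if pixel_pitch_um is None else pixel_pitch_um
        segs = self._selected(state)
        mask = rasterize_segments(segs, self.field_size_um, pitch, dilation_factor)
        return TruthMetrics(
            area_fraction=float(mask.mean()),
            centerline_length_per_area=self.centerline_length_um(state) / 1000.0 / self.field_area_mm2,
            branch_count=self.branch_count(state),
        )

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "field_size_um": list(self.field_size_um),
            "raster_pitch_um": self.raster_pitch_um,
            "seed": self.seed,
            "segments": [
                {
                    "start_um": list(s.start_um),
                    "end_um": list(s.end_um),
                    "diameter_um": s.diameter_um,
                    "perfused_baseline": s.perfused_baseline,
                    "nodes": list(s.nodes),
                }
                for s in self.segments
            ],
            "truth_metrics": {k: asdict(v) for k, v in self.truth_metrics.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkTruth":
        payload = json.loads(Path(path).read_text())
        segs = [
            Segment(
                tuple(s["start_um"]),
                tuple(s["end_um"]),
                s["diameter_um"],
                s["perfused_baseline"],
                tuple(s["nodes"]),
            )
            for s in payload["segments"]
        ]
        truth = {k: TruthMetrics(**v) for k, v in payload["truth_metrics"].items()}
        return cls(
            segments=segs,
            field_size_um=tuple(payload["field_size_um"]),
            truth_metrics=truth,
            raster_pitch_um=payload["raster_pitch_um"],
            seed=payload["seed"],
        )


# ---------------------------------------------------------------------------
# rasterization


def rasterize_segments(
    segments: Sequence[Segment],
    field_size_um: tuple[float, float],
    pixel_pitch_um: float,
    dilation_factor: float = 1.0,
) -> np.ndarray:
    """Rasterize segments as filled capsules (distance to segment <= d/2).

    Pixel (row i, col j) is centered at ((j + 0.5) * pitch, (i + 0.5) * pitch)
    in (x, y) micrometer coordinates; no anti-aliasing.
    """
    w_um, h_um = field_size_um
    W = int(round(w_um / pixel_pitch_um))
    H = int(round(h_um / pixel_pitch_um))
    mask = np.zeros((H, W), dtype=bool)
    for s in segments:
        r = 0.5 * s.diameter_um * dilation_factor
        x0, y0 = s.start_um
        x1, y1 = s.end_um
        # bounding box in pixel indices, inclusive of the capsule radius
        jmin = max(int((min(x0, x1) - r) / pixel_pitch_um) - 1, 0)
        jmax = min(int((max(x0, x1) + r) / pixel_pitch_um) + 2, W)
        imin = max(int((min(y0, y1) - r) / pixel_pitch_um) - 1, 0)
        imax = min(int((max(y0, y1) + r) / pixel_pitch_um) + 2, H)
        if jmin >= jmax or imin >= imax:
            continue
        xs = (np.arange(jmin, jmax) + 0.5) * pixel_pitch_um
        ys = (np.arange(imin, imax) + 0.5) * pixel_pitch_um
        X, Y = np.meshgrid(xs, ys)
        dx, dy = x1 - x0, y1 - y0
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            dist2 = (X - x0) ** 2 + (Y - y0) ** 2
        else:
            t = np.clip(((X - x0) * dx + (Y - y0) * dy) / seg_len2, 0.0, 1.0)
            dist2 = (X - (x0 + t * dx)) ** 2 + (Y - (y0 + t * dy)) ** 2
        mask[imin:imax, jmin:jmax] |= dist2 <= r * r
    return mask


# ---------------------------------------------------------------------------
# network growth


def _unit(theta: float) -> np.ndarray:
    return np.array([np.cos(theta), np.sin(theta)])


#: Default field: the nominal 6 x 6 mm scan is 924 x 924 px at 6.5 um/px,
#: i.e. exactly 6.006 mm on a side.
DEFAULT_FIELD_MM = (6.006, 6.006)


def generate_network(
    field_size_mm: float | tuple[float, float] = DEFAULT_FIELD_MM,
    target_density: float = 0.25,
    branching_params: Optional[BranchingParams] = None,
    seed: int = 0,
    raster_pitch_um: float = 6.5,
) -> NetworkTruth:
    """Grow a branching vascular network to a target rendered density.

    Trees are grown tip-by-tip: each active tip extends into one or two
    child segments whose direction lies inside a cone around the parent
    direction, with length and diameter drawn from the distributions in
    ``branching_params``. When all tips terminate before the target
    density is reached, a new branch is seeded from a random existing
    node. Growth stops once the rasterized area fraction (measured at a
    coarse pitch for speed) reaches ``target_density``; the final truth
    area fraction is measured at ``raster_pitch_um``.

    Terminal branches are flagged unperfused at baseline with probability
    ``unperfused_terminal_frac``, emulating capillaries recruited only at
    the reactive-hyperemia peak.
    """
    bp = branching_params or BranchingParams()
    if np.isscalar(field_size_mm):
        field_size_mm = (float(field_size_mm), float(field_size_mm))
    w_um, h_um = field_size_mm[0] * 1000.0, field_size_mm[1] * 1000.0
    if w_um <= 0 or h_um <= 0:
        raise ValueError("field size must be positive")
    if not 0.0 < target_density < 0.6:
        raise ValueError("target_density must be in (0, 0.6)")

    rng = np.random.default_rng(seed)
    margin = bp.max_diameter_um  # keep endpoints safely inside the field

    segments: list[Segment] = []
    seg_a: list[np.ndarray] = []  # start points, for clearance checks
    seg_b: list[np.ndarray] = []
    seg_r: list[float] = []  # radii
    node_pos: list[np.ndarray] = []
    node_dir: list[np.ndarray] = []
    node_diam: list[float] = []
    node_segments: list[list[int]] = []  # incident segment indices per node
    inbound: dict[int, int] = {}  # node id -> inbound segment index
    has_child: list[bool] = []  # per-segment terminality bookkeeping
    tips: list[int] = []  # node ids with growth potential

    def new_node(pos: np.ndarray, direction: np.ndarray, diam: float) -> int:
        node_pos.append(pos)
        node_dir.append(direction)
        node_diam.append(diam)
        node_segments.append([])
        return len(node_pos) - 1

    def inside(p: np.ndarray) -> bool:
        return margin <= p[0] <= w_um - margin and margin <= p[1] <= h_um - margin

    arrays = {"n": -1}  # cached segment geometry, rebuilt when stale

    def seg_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if arrays["n"] != len(segments):
            arrays["A"] = np.asarray(seg_a)
            arrays["AB"] = np.asarray(seg_b) - arrays["A"]
            arrays["R"] = np.asarray(seg_r)
            arrays["denom"] = np.maximum((arrays["AB"] ** 2).sum(axis=1), 1e-12)
            arrays["n"] = len(segments)
        return arrays["A"], arrays["AB"], arrays["R"]

    def clearance_ok(p0: np.ndarray, p1: np.ndarray, radius: float, parent: int) -> bool:
        """Self-avoidance: the new capsule must keep a clearance gap from
        every existing segment not incident to its start node."""
        if not segments:
            return True
        A, AB, R = seg_arrays()
        denom = arrays["denom"]
        ts = np.linspace(0.0, 1.0, 12)
        P = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]  # (12, 2)
        AP = P[:, None, :] - A[None, :, :]  # (12, n, 2)
        t = np.clip((AP * AB[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
        D = AP - t[:, :, None] * AB[None, :, :]
        gap = np.sqrt((D**2).sum(axis=2)) - (R[None, :] + radius)
        gap = gap.min(axis=0)
        for sidx in node_segments[parent]:
            gap[sidx] = np.inf  # incident segments share the junction blob
        return bool(gap.min() >= bp.clearance_um)

    def add_segment(parent: int, direction: np.ndarray, diam: float) -> Optional[int]:
        length = rng.uniform(*bp.segment_length_um)
        end = node_pos[parent] + direction * length
        if not inside(end):
            return None
        if not clearance_ok(node_pos[parent], end, diam / 2.0, parent):
            return None
        child = new_node(end, direction, diam)
        segments.append(
            Segment(
                tuple(node_pos[parent]),
                tuple(end),
                float(diam),
                True,  # perfusion flags assigned after growth
                (parent, child),
            )
        )
        seg_a.append(node_pos[parent])
        seg_b.append(end)
        seg_r.append(diam / 2.0)
        has_child.append(False)
        sidx = len(segments) - 1
        node_segments[parent].append(sidx)
        node_segments[child].append(sidx)
        inbound[child] = sidx
        return child

    def free_gap(p: np.ndarray) -> float:
        """Distance from a point to the nearest vessel wall."""
        if not segments:
            return np.inf
        A, AB, R = seg_arrays()
        t = np.clip(((p - A) * AB).sum(axis=1) / arrays["denom"], 0.0, 1.0)
        D = p - (A + t[:, None] * AB)
        return float((np.sqrt((D**2).sum(axis=1)) - R).min())

    def sprout_from(parent: int, diam: float) -> bool:
        # sprout direction must separate clearly from every segment already
        # incident to the node: acute wedges between thick adjacent capsules
        # leave long apex ridges in the rendered mask that read as spurious
        # junctions, so branches must leave at an obtuse angle (~100 deg)
        incident_theta = []
        for sidx in node_segments[parent]:
            s = segments[sidx]
            ref = s.start_um if s.nodes[1] == parent else s.end_um
            incident_theta.append(
                np.arctan2(ref[1] - node_pos[parent][1], ref[0] - node_pos[parent][0])
            )
        thetas = rng.uniform(0, 2 * np.pi, size=24)
        feasible = [
            th
            for th in thetas
            if all(
                abs((th - t0 + np.pi) % (2 * np.pi) - np.pi) > 1.75
                for t0 in incident_theta
            )
        ]
        for theta in feasible[:4]:
            child = add_segment(parent, _unit(theta), diam)
            if child is not None:
                tips.append(child)
                return True
        return False

    def seed_tree() -> None:
        if node_pos and rng.random() < 0.7:
            # sprout a new branch from a random existing node; cap the node
            # degree at 4 so junctions stay simple, resolvable Ys and Xs
            for _try in range(10):
                cand = int(rng.integers(len(node_pos)))
                if len(node_segments[cand]) > 3:
                    continue
                diam = float(
                    np.clip(
                        node_diam[cand] * rng.uniform(*bp.diameter_decay),
                        bp.min_diameter_um,
                        bp.max_diameter_um,
                    )
                )
                if sprout_from(cand, diam):
                    return
            return
        # best-candidate seeding: of several random positions take the
        # one farthest from the existing network, so late trunks land in
        # the remaining voids instead of being clearance-rejected
        cands = np.column_stack(
            [
                rng.uniform(margin, w_um - margin, size=25),
                rng.uniform(margin, h_um - margin, size=25),
            ]
        )
        pos = cands[int(np.argmax([free_gap(c) for c in cands]))]
        diam = rng.uniform(*bp.trunk_diameter_um)
        parent = new_node(pos, _unit(rng.uniform(0, 2 * np.pi)), diam)
        sprout_from(parent, diam)

    def grow_tip(tip: int) -> None:
        n_children = 2 if rng.random() < bp.bifurcation_prob else 1
        # a queued tip may have gained extra branches from seed_tree in the
        # meantime; never let any node exceed degree 4
        n_children = min(n_children, 4 - len(node_segments[tip]))
        if n_children <= 0:
            return
        parent_theta = float(np.arctan2(node_dir[tip][1], node_dir[tip][0]))
        cone = np.deg2rad(bp.cone_half_angle_deg)

        def incident_thetas() -> list[float]:
            out = []
            for sidx in node_segments[tip]:
                s = segments[sidx]
                ref = s.start_um if s.nodes[1] == tip else s.end_um
                out.append(
                    np.arctan2(ref[1] - node_pos[tip][1], ref[0] - node_pos[tip][0])
                )
            return out

        for k in range(n_children):
            diam = float(
                np.clip(
                    node_diam[tip] * rng.uniform(*bp.diameter_decay),
                    bp.min_diameter_um,
                    bp.max_diameter_um,
                )
            )
            existing = incident_thetas()
            for _attempt in range(6):
                if n_children == 2:
                    # a blunt minimum branching angle keeps the wedge between
                    # sibling vessels short, so the rendered junction blob
                    # stays centered on the analytic node
                    sign = 1.0 if k == 0 else -1.0
                    theta = parent_theta + sign * rng.uniform(0.55, cone)
                else:
                    theta = parent_theta + rng.uniform(-cone, cone)
                # keep a blunt wedge against every arm already at this node,
                # including branches seeded onto it after it was queued
                if any(
                    abs((theta - t0 + np.pi) % (2 * np.pi) - np.pi) < 1.1
                    for t0 in existing
                ):
                    continue
                child = add_segment(tip, _unit(theta), diam)
                if child is not None:
                    if tip in inbound:
                        has_child[inbound[tip]] = True
                    tips.append(child)
                    break

    def measured_density() -> float:
        coarse = max(raster_pitch_um, 13.0)
        return float(rasterize_segments(segments, (w_um, h_um), coarse).mean())

    for _ in range(bp.n_seed_trees):
        seed_tree()

    max_rounds = 400
    stall = 0
    last_density = 0.0
    for _round in range(max_rounds):
        if bp.max_segments is not None and len(segments) >= bp.max_segments:
            segments = segments[: bp.max_segments]
            has_child = has_child[: bp.max_segments]
            break
        wave, tips = tips[:40], tips[40:]
        for tip in wave:
            grow_tip(tip)
            if bp.max_segments is not None and len(segments) >= bp.max_segments:
                break
        if len(tips) < 10:
            # rejection has starved the tip pool; reseed from the existing
            # network (or fresh trunks) to keep filling space
            for _ in range(20):
                seed_tree()
        dens = measured_density()
        if dens >= target_density:
            break
        if dens <= last_density + 1e-4:
            stall += 1
            if stall > 60:
                if dens >= 0.8 * target_density:
                    break  # stalled inside the +-20% tolerance: accept
                raise DensityUnreachableError(
                    f"density stalled at {dens:.3f} < target {target_density:.3f} "
                    "with the given branching parameters"
                )
        else:
            stall = 0
        last_density = dens
    else:
        if measured_density() < 0.8 * target_density:
            raise DensityUnreachableError(
                f"target density {target_density:.3f} not reached in {max_rounds} rounds"
            )

    # perfusion flags: a fraction of terminal branches is unperfused at rest
    terminal = [not c for c in has_child]
    flagged: list[Segment] = []
    for s, is_term in zip(segments, terminal):
        perfused = True
        if is_term and rng.random() < bp.unperfused_terminal_frac:
            perfused = False
        flagged.append(
            Segment(s.start_um, s.end_um, s.diameter_um, perfused, s.nodes)
        )

    net = NetworkTruth(
        segments=flagged,
        field_size_um=(w_um, h_um),
        raster_pitch_um=raster_pitch_um,
        seed=seed,
    )
    for state in ("baseline", "compressed", "hyperemia"):
        net.truth_metrics[state] = net.compute_truth(state)
    return net


# ---------------------------------------------------------------------------
# rendering


def render_enface(
    network: NetworkTruth,
    state: str,
    dilation_factor: float = 1.05,
    pixel_pitch_um: float = 6.5,
    background_level: float = 0.05,
    vessel_level: float = 0.85,
) -> tuple[EnFaceImage, TruthMetrics]:
    """Render one perfusion state of a network into an en-face image.

    baseline draws only baseline-perfused segments at nominal diameter;
    hyperemia draws every segment with diameters scaled by
    ``dilation_factor``; compressed draws background only (full flow
    inhibition under probe pressure). The returned truth metrics describe
    exactly the rendered subset and diameters.
    """
    if dilation_factor < 1.0:
        raise ValueError("dilation_factor must be >= 1")
    w_um, h_um = network.field_size_um
    for extent in (w_um, h_um):
        n = extent / pixel_pitch_um
        if abs(n - round(n)) > 1e-6 or round(n) < 1:
            raise ValueError(
                f"pixel pitch {pixel_pitch_um} um does not evenly divide the "
                f"{extent} um field"
            )
    factor = dilation_factor if state == "hyperemia" else 1.0
    segs = network._selected(state) if state != "compressed" else []
    mask = rasterize_segments(segs, network.field_size_um, pixel_pitch_um, factor)
    pixels = np.full(mask.shape, background_level, dtype=np.float64)
    pixels[mask] = vessel_level
    truth = TruthMetrics(
        area_fraction=float(mask.mean()),
        centerline_length_per_area=network.centerline_length_um(state) / 1000.0 / network.field_area_mm2,
        branch_count=network.branch_count(state),
    )
    image = EnFaceImage(pixels, pixel_pitch_um=pixel_pitch_um, state=state)
    return image, truth


def add_artifacts(image: EnFaceImage, params: ArtifactParams) -> EnFaceImage:
    """Inject multiplicative speckle then additive scan stripes.

    Speckle is gamma-distributed with unit mean and coefficient of
    variation ``speckle_contrast``; stripes are a per-line constant offset
    drawn uniformly in +-stripe_amplitude of the dynamic range. For
    ``stripe_axis="fast"`` the offset is constant within each column and
    varies across columns. Output is clipped to [0, 1]. Deterministic for
    a fixed ``params.seed``.
    """
    pixels = image.pixels.copy()
    if params.speckle_contrast == 0.0 and params.stripe_amplitude == 0.0 and params.background_level == 0.0:
        return image.with_pixels(pixels)
    rng = np.random.default_rng(params.seed)
    if params.background_level > 0.0:
        pixels = pixels + params.background_level
    if params.speckle_contrast > 0.0:
        shape = 1.0 / params.speckle_contrast**2
        speckle = rng.gamma(shape, scale=1.0 / shape, size=pixels.shape)
        pixels = pixels * speckle
    if params.stripe_amplitude > 0.0:
        h, w = pixels.shape
        if params.stripe_axis == "fast":
            offsets = rng.uniform(-1.0, 1.0, size=w) * params.stripe_amplitude
            pixels = pixels + offsets[None, :]
        else:
            offsets = rng.uniform(-1.0, 1.0, size=h) * params.stripe_amplitude
            pixels = pixels + offsets[:, None]
    return image.with_pixels(np.clip(pixels, 0.0, 1.0))


def render_histology_stack(
    network: NetworkTruth,
    n_sections: int = 10,
    depth_range_um: tuple[float, float] = (40.0, 440.0),
    jitter_px: int = 3,
    shrinkage: float = 0.9,
    seed: int = 0,
    pixel_pitch_um: float = 6.5,
    background_level: float = 0.05,
    vessel_level: float = 0.85,
    offsets: Optional[Sequence[tuple[int, int]]] = None,
) -> HistologyStack:
    """Render serial horizontal sections of the full network.

    Histology visualizes the entire vascular bed independently of
    perfusion, so every segment is drawn in every section. Tissue
    processing is emulated by an isotropic shrinkage of geometry (and
    diameters) about the field center and an integer per-section
    translation of magnitude <= ``jitter_px`` (section 1 is the
    reference and never shifted). Section depths are evenly spaced over
    ``depth_range_um`` including both endpoints; true offsets are stored
    for registration tests.
    """
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    if not 0.0 < shrinkage <= 1.0:
        raise ValueError("shrinkage must be in (0, 1]")
    lo, hi = depth_range_um
    if not lo < hi:
        raise ValueError("depth range must be increasing")
    rng = np.random.default_rng(seed)
    depths = np.linspace(lo, hi, n_sections)

    cx, cy = network.field_size_um[0] / 2.0, network.field_size_um[1] / 2.0

    def shrink(p: tuple[float, float]) -> tuple[float, float]:
        return (cx + (p[0] - cx) * shrinkage, cy + (p[1] - cy) * shrinkage)

    shrunk = [
        Segment(shrink(s.start_um), shrink(s.end_um), s.diameter_um * shrinkage, s.perfused_baseline, s.nodes)
        for s in network.segments
    ]
    mask = rasterize_segments(shrunk, network.field_size_um, pixel_pitch_um)
    base = np.full(mask.shape, background_level, dtype=np.float64)
    base[mask] = vessel_level

    if offsets is not None:
        true_offsets = np.asarray(offsets, dtype=int)
        if true_offsets.shape != (n_sections, 2):
            raise ValueError("offsets must be one (dy, dx) pair per section")
    else:
        true_offsets = rng.integers(-jitter_px, jitter_px + 1, size=(n_sections, 2))
        true_offsets[0] = (0, 0)

    sections = np.empty((n_sections,) + base.shape, dtype=np.float64)
    for i, (dy, dx) in enumerate(true_offsets):
        shifted = np.full_like(base, background_level)
        h, w = base.shape
        ys = slice(max(dy, 0), min(h + dy, h))
        xs = slice(max(dx, 0), min(w + dx, w))
        ys_src = slice(max(-dy, 0), min(h - dy, h))
        xs_src = slice(max(-dx, 0), min(w - dx, w))
        shifted[ys, xs] = base[ys_src, xs_src]
        sections[i] = shifted

    return HistologyStack(
        sections=sections,
        depths_um=depths,
        pixel_pitch_um=pixel_pitch_um,
        true_offsets=true_offsets,
    )
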