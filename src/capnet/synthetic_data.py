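"""Synthetic capillary networks, velocity traces, OCTA depth stacks and
straightened vessel images with known ground truth.

The generator realizes the world the analysis assumes:

* each feeding arteriole (> 8 um lumen) bifurcates through ``tree_depth``
  generations down to terminal capillaries (~4.33 +/- 0.9 um), which drain
  pairwise through confluences into a collecting venule;
* every junction's radii satisfy the power-law identity
  r_major**x = r_minor1**x + r_minor2**x exactly at that junction's drawn
  true exponent, so exponent fits can be checked against construction;
* vessel depths follow a two-peak mixture (150 and 200 um above PR1);
* velocity traces are raised-cosine cardiac waveforms whose pulsatility
  decays, and whose diastolic (minimum) velocity rises, with distance from
  the feeder; an optional calibration mode chooses regression slopes so a
  stated target Pearson r between a covariate and a response is embedded.

All generators are pure functions of (config, seed): a single
``numpy.random.Generator`` stream per call, no global state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .diameter_estimation import StraightenedVessel, _blurred_band_cdf_integral
from .errors import ConfigurationError, GenerationError
from .flow_metrics import VelocityTrace
from .network_model import (
    CapillaryType,
    VascularNetwork,
    build_network,
    identify_feeders,
)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Stated world of the generator; defaults mirror the measured cohort."""

    seed: int = 0
    n_feeders: int = 1
    tree_depth: int = 3                       # bifurcation generations per feeder
    # junction exponents: fixed value wins over the (mean, sd) distribution
    true_exponent: Optional[float] = None
    true_exponent_dist: tuple = (2.2, 0.7)    # clipped to exponent_bounds
    exponent_bounds: tuple = (1.0, 4.5)
    capillary_diameter_dist: tuple = (4.33, 0.9)   # um (terminal capillaries)
    feeder_diameter_min: float = 8.0               # um
    # two-component depth mixture: (mean um, sd um, weight)
    depth_mixture: tuple = ((150.0, 10.0, 2.0 / 3.0), (200.0, 10.0, 1.0 / 3.0))
    depth_bounds: tuple = (70.0, 215.0)            # keep depths inside the scan range
    segment_length_dist: tuple = (75.0, 25.0)      # um
    unorthodox_fraction: float = 0.0               # confluence-then-bifurcation segments
    # velocity traces
    sampling_rate: float = 200.0                   # Hz, in {200, 300}
    duration: float = 3.0                          # s
    cardiac_freq: float = 1.0                      # Hz (60 bpm; integer cycles over 3 s)
    vave_base: float = 2.0                         # mm/s
    vave_sd: float = 0.3                           # mm/s between-vessel scatter
    vmin_sd: float = 0.15                          # mm/s between-vessel scatter
    pulsatility_at_feeder: float = 0.55            # P0, unitless
    pulsatility_decay: float = 5.0e-4              # per um (linear) or 1/tau (exponential)
    decay_model: str = "linear"                    # "linear" | "exponential"
    pulsatility_jitter: float = 0.03
    vmin_slope: Optional[float] = None             # (mm/s)/um; overrides the P(d) coupling
    je_vave_slope: float = 0.0                     # (mm/s) per exponent unit
    # calibration mode: embed a stated target Pearson r instead of raw slopes
    target_r_je_vave: Optional[float] = None
    target_r_dist_vmin: Optional[float] = None
    trace_noise_sd: float = 0.05                   # mm/s per-sample noise
    # depth stack rendering
    depth_labels: tuple = tuple(range(60, 221, 20))  # um from PR1
    slab_thickness: float = 40.0                   # um
    depth_sigma: float = 20.0                      # um, half the slab thickness
    depth_signal_amplitude: float = 50.0           # gray levels
    depth_noise_sd: float = 10.0                   # gray levels (SNR 5 by default)
    depth_background: float = 20.0                 # gray levels

    def validate(self) -> None:
        if self.n_feeders < 1 or self.tree_depth < 1:
            raise ConfigurationError("n_feeders and tree_depth must be >= 1")
        sds = [
            self.true_exponent_dist[1],
            self.capillary_diameter_dist[1],
            self.segment_length_dist[1],
            self.vave_sd,
            self.vmin_sd,
            self.pulsatility_jitter,
            self.trace_noise_sd,
            self.depth_noise_sd,
        ] + [c[1] for c in self.depth_mixture]
        if any(s < 0 for s in sds):
            raise ConfigurationError("all standard deviations must be >= 0")
        w = sum(c[2] for c in self.depth_mixture)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"depth mixture weights sum to {w}, expected 1")
        if self.sampling_rate not in (200, 300):
            raise ConfigurationError("sampling_rate must be 200 or 300 Hz")
        n = self.sampling_rate * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration * sampling_rate must be an integer")
        if not 0 <= self.unorthodox_fraction <= 1:
            raise ConfigurationError("unorthodox_fraction must lie in [0, 1]")
        if self.decay_model not in ("linear", "exponential"):
            raise ConfigurationError("decay_model must be 'linear' or 'exponential'")


@dataclass
class GroundTruth:
    """Per-junction and per-segment truth for parameter-recovery tests."""

    exponents: dict = field(default_factory=dict)        # junction_id -> x
    diameter: dict = field(default_factory=dict)         # segment -> um
    depth: dict = field(default_factory=dict)            # segment -> um
    branch_order: dict = field(default_factory=dict)     # segment -> int
    feeder_distance: dict = field(default_factory=dict)  # segment -> um
    capillary_type: dict = field(default_factory=dict)   # segment -> str
    je_upstream: dict = field(default_factory=dict)      # segment -> x of supplying bifurcation
    je_downstream: dict = field(default_factory=dict)    # segment -> x of collecting confluence
    flow: dict = field(default_factory=dict)             # segment -> waveform parameters
    voi_ids: list = field(default_factory=list)          # terminal capillaries


def slope_for_target_r(target_r: float, noise_sd: float, covariate_sd: float) -> float:
    """Regression slope embedding Pearson r = *target_r* for a response
    b*x + noise, given the covariate and noise standard deviations."""
    if not -1 < target_r < 1:
        raise ConfigurationError("target r must lie strictly inside (-1, 1)")
    if covariate_sd <= 0:
        raise ConfigurationError("covariate has zero spread; cannot embed a correlation")
    return target_r / math.sqrt(1.0 - target_r**2) * noise_sd / covariate_sd


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------


def _draw_exponent(rng, config: SyntheticConfig) -> float:
    if config.true_exponent is not None:
        return float(config.true_exponent)
    mu, sd = config.true_exponent_dist
    lo, hi = config.exponent_bounds
    return float(np.clip(rng.normal(mu, sd), lo, hi))


def generate_network(config: SyntheticConfig) -> tuple:
    """Build a feeder -> bifurcation tree -> confluence tree network.

    Every junction's radii satisfy the exponent identity exactly at the
    drawn true exponent. Returns ``(VascularNetwork, GroundTruth)``; the
    network is assembled through :func:`build_network` from the same tables
    the CSV writers emit, so file round-trips are exact.
    """
    config.validate()
    rng = np.random.default_rng([0, config.seed])
    truth = GroundTruth()

    seg_rows = []    # id, length_um, diameter_um
    edge_rows = []   # junction_id, kind, parent_id, daughter1_id, daughter2_id
    up_len: dict = {}    # summed full lengths of strictly-upstream segments

    counters = {"seg": 0, "junc": 0}

    def new_seg(radius, order, upstream, seg_type):
        counters["seg"] += 1
        sid = f"V{counters['seg']:04d}"
        length = float(max(15.0, rng.normal(*config.segment_length_dist)))
        seg_rows.append({"id": sid, "length_um": length, "diameter_um": 2 * radius})
        truth.diameter[sid] = 2 * radius
        truth.branch_order[sid] = order
        up_len[sid] = upstream
        truth.feeder_distance[sid] = upstream + length / 2.0
        truth.capillary_type[sid] = seg_type
        return sid, length

    def new_junction(kind, major, minors, x):
        counters["junc"] += 1
        jid = f"J{counters['junc']:04d}"
        edge_rows.append(
            {
                "junction_id": jid,
                "kind": kind,
                "parent_id": major,
                "daughter1_id": minors[0],
                "daughter2_id": minors[1],
            }
        )
        truth.exponents[jid] = x
        return jid

    x_mean = config.true_exponent if config.true_exponent is not None else config.true_exponent_dist[0]

    for _ in range(config.n_feeders):
        cap_r = config.capillary_diameter_dist[0] / 2.0
        r_feeder = cap_r * 2.0 ** (config.tree_depth / x_mean) * float(np.exp(rng.normal(0, 0.05)))
        r_feeder = max(r_feeder, config.feeder_diameter_min * 1.1 / 2.0)
        fid, flen = new_seg(r_feeder, 1, 0.0, CapillaryType.UNCLASSIFIED.value)

        # arterial bifurcation tree (top-down; identity exact by construction)
        level = [(fid, r_feeder, flen, 1, 0.0)]  # (id, radius, length, order, up_len)
        for gen in range(1, config.tree_depth + 1):
            nxt = []
            terminal = gen == config.tree_depth
            seg_type = CapillaryType.TC.value if terminal else CapillaryType.AC.value
            for pid, r_p, l_p, order, up in level:
                x = _draw_exponent(rng, config)
                share = float(rng.uniform(0.35, 0.65))
                r1 = r_p * share ** (1.0 / x)
                r2 = r_p * (1.0 - share) ** (1.0 / x)
                child_up = up + l_p
                s1, l1 = new_seg(r1, order + 1, child_up, seg_type)
                s2, l2 = new_seg(r2, order + 1, child_up, seg_type)
                jid = new_junction("BIFURCATION", pid, (s1, s2), x)
                truth.je_upstream[s1] = x
                truth.je_upstream[s2] = x
                nxt.append((s1, r1, l1, order + 1, child_up))
                nxt.append((s2, r2, l2, order + 1, child_up))
            level = nxt

        # venous confluence tree (bottom-up; collector radius from the identity)
        inputs = level  # terminal capillaries
        venous_level = 0
        while len(inputs) > 1:
            venous_level += 1
            nxt = []
            for i in range(0, len(inputs) - 1, 2):
                (s1, r1, l1, o1, u1), (s2, r2, l2, o2, u2) = inputs[i], inputs[i + 1]
                x = _draw_exponent(rng, config)
                r_c = (r1**x + r2**x) ** (1.0 / x)
                # shortest-upstream-path rule the analysis uses: min summed length
                c1, c2 = u1 + l1, u2 + l2
                up_c, order_c = (c1, o1) if (c1, s1) <= (c2, s2) else (c2, o2)
                c_type = CapillaryType.VC.value
                cid, cl = new_seg(r_c, order_c, up_c, c_type)
                jid = new_junction("CONFLUENCE", cid, (s1, s2), x)
                truth.je_downstream[s1] = x
                truth.je_downstream[s2] = x
                if venous_level == 1 and rng.random() < config.unorthodox_fraction:
                    # "unorthodox" capillary: collecting junction before the
                    # supplying one along the flow direction
                    truth.capillary_type[cid] = CapillaryType.WC.value
                    xb = _draw_exponent(rng, config)
                    share = float(rng.uniform(0.35, 0.65))
                    rb1 = r_c * share ** (1.0 / xb)
                    rb2 = r_c * (1.0 - share) ** (1.0 / xb)
                    b1, bl1 = new_seg(rb1, order_c + 1, up_c + cl, CapillaryType.TC.value)
                    b2, bl2 = new_seg(rb2, order_c + 1, up_c + cl, CapillaryType.TC.value)
                    new_junction("BIFURCATION", cid, (b1, b2), xb)
                    truth.je_upstream[b1] = xb
                    truth.je_upstream[b2] = xb
                    nxt.append((b1, rb1, bl1, order_c + 1, up_c + cl))
                    nxt.append((b2, rb2, bl2, order_c + 1, up_c + cl))
                else:
                    nxt.append((cid, r_c, cl, order_c, up_c))
            if len(inputs) % 2 == 1:
                nxt.append(inputs[-1])
            inputs = nxt
        # the final collector is the venule: no downstream junction
        truth.capillary_type[inputs[0][0]] = CapillaryType.UNCLASSIFIED.value

    # depths for every segment
    means = np.array([c[0] for c in config.depth_mixture])
    sds = np.array([c[1] for c in config.depth_mixture])
    weights = np.array([c[2] for c in config.depth_mixture])
    for row in seg_rows:
        comp = rng.choice(len(means), p=weights)
        d = float(np.clip(rng.normal(means[comp], sds[comp]), *config.depth_bounds))
        truth.depth[row["id"]] = d
        row["depth_um_true"] = d

    truth.voi_ids = sorted(
        s for s, t in truth.capillary_type.items() if t == CapillaryType.TC.value
    )

    seg_df = pd.DataFrame(seg_rows)
    edge_df = pd.DataFrame(edge_rows)
    net = build_network(seg_df, edge_df)
    identify_feeders(net, min_diameter=config.feeder_diameter_min)
    for sid, seg in net.segments.items():
        seg.depth = truth.depth[sid]
    return net, truth


def network_tables(net: VascularNetwork, truth: Optional[GroundTruth] = None) -> tuple:
    """Serialize a network to (segments, edges) data frames."""
    seg_rows = []
    for sid in sorted(net.segments):
        s = net.segments[sid]
        row = {"id": sid, "length_um": s.length, "diameter_um": s.diameter}
        if truth is not None:
            row["depth_um_true"] = truth.depth.get(sid)
        seg_rows.append(row)
    edge_rows = [
        {
            "junction_id": jid,
            "kind": j.kind.value,
            "parent_id": j.major_id,
            "daughter1_id": j.minor_ids[0],
            "daughter2_id": j.minor_ids[1],
        }
        for jid, j in sorted(net.junctions.items())
    ]
    return pd.DataFrame(seg_rows), pd.DataFrame(edge_rows)


# ---------------------------------------------------------------------------
# velocity traces
# ---------------------------------------------------------------------------


def generate_velocity_traces(
    net: VascularNetwork, truth: GroundTruth, config: SyntheticConfig
) -> dict:
    """Raised-cosine cardiac velocity traces for every segment.

    v(t) = V_ave * (1 + P * cos(2 pi f t + phi)) + noise, with the phase
    drawn on the sample lattice so the sampled extrema hit V_min and V_max
    exactly when noise is zero. Pulsatility follows the configured decay
    with feeder distance; the minimum (diastolic) velocity rises with
    distance; mean velocity optionally depends on the collecting-junction
    exponent (raw slope or calibrated to a target correlation).
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    sids = sorted(net.segments)
    for sid in sids:
        if sid not in truth.feeder_distance:
            raise GenerationError(f"segment {sid} has no ground-truth feeder distance")
    dist = np.array([truth.feeder_distance[s] for s in sids])
    je = np.array([truth.je_downstream.get(s, np.nan) for s in sids])
    je_mean = np.nanmean(je) if np.isfinite(je).any() else 0.0
    je_dev = np.where(np.isfinite(je), je - je_mean, 0.0)

    # calibration targets refer to the analyzed cohort (the terminal
    # capillaries), so covariate spreads are taken over that subset
    cohort = [i for i, s in enumerate(sids) if s in set(truth.voi_ids)] or list(range(len(sids)))

    # mean velocity model
    if config.target_r_je_vave is not None:
        sd_je = float(np.nanstd(je[cohort]))
        b_je = slope_for_target_r(config.target_r_je_vave, config.vave_sd, sd_je)
    else:
        b_je = config.je_vave_slope
    v_ave = config.vave_base + b_je * je_dev + rng.normal(0.0, config.vave_sd, len(sids))
    v_ave = np.clip(v_ave, 0.2, None)

    # pulsatility profile with feeder distance
    if config.decay_model == "linear":
        p_d = config.pulsatility_at_feeder - config.pulsatility_decay * dist
    else:
        p_d = config.pulsatility_at_feeder * np.exp(-config.pulsatility_decay * dist)
    p_d = np.clip(p_d, 0.02, 0.95)

    # minimum (diastolic) velocity model
    if config.target_r_dist_vmin is not None or config.vmin_slope is not None:
        if config.target_r_dist_vmin is not None:
            slope = slope_for_target_r(
                config.target_r_dist_vmin, config.vmin_sd, float(np.std(dist[cohort]))
            )
        else:
            slope = config.vmin_slope
        vmin_center = config.vave_base * (1.0 - float(np.mean(p_d)))
        v_min = (
            vmin_center
            + slope * (dist - float(np.mean(dist)))
            + rng.normal(0.0, config.vmin_sd, len(sids))
        )
    else:
        jitter = rng.normal(0.0, config.pulsatility_jitter, len(sids))
        v_min = v_ave * (1.0 - np.clip(p_d + jitter, 0.02, 0.95))
    v_min = np.clip(v_min, 0.05, 0.98 * v_ave)
    v_max = 2.0 * v_ave - v_min
    puls = (v_max - v_min) / (v_max + v_min)

    n = int(round(config.sampling_rate * config.duration))
    t = np.arange(n) / config.sampling_rate
    omega = 2.0 * np.pi * config.cardiac_freq
    phase_step = omega / config.sampling_rate
    traces = {}
    for i, sid in enumerate(sids):
        phi = float(rng.integers(0, n)) * phase_step  # lattice phase: exact extrema
        v = v_ave[i] * (1.0 + puls[i] * np.cos(omega * t + phi))
        if config.trace_noise_sd > 0:
            v = v + rng.normal(0.0, config.trace_noise_sd, n)
        v = np.maximum(v, 1e-3)  # velocities are positive after clamping
        traces[sid] = VelocityTrace(samples=v, rate=config.sampling_rate, vessel_id=sid)
        truth.flow[sid] = {
            "v_ave": float(v_ave[i]),
            "v_min": float(v_min[i]),
            "v_max": float(v_max[i]),
            "pulsatility": float(puls[i]),
            "phase": phi,
        }
    return traces


# ---------------------------------------------------------------------------
# OCTA depth stack
# ---------------------------------------------------------------------------


def generate_depth_stack(
    net: VascularNetwork,
    truth: GroundTruth,
    config: SyntheticConfig,
    segment_ids=None,
    cell_px: int = 8,
    roi_px: int = 4,
) -> tuple:
    """Slab stack plus per-vessel ROI masks.

    Each vessel occupies a small square ROI on a grid; its ROI intensity is
    a Gaussian bell in depth centred on the true depth (sigma =
    ``depth_sigma``, about half the 40 um slab thickness) over a noisy
    background. Returns ``(DepthStack, {segment_id: bool mask})``.
    """
    from .depth_profiles import DepthStack

    config.validate()
    rng = np.random.default_rng([2, config.seed])
    if segment_ids is None:
        segment_ids = sorted(truth.depth)
    labels = np.asarray(config.depth_labels, dtype=float)
    for sid in segment_ids:
        d = truth.depth.get(sid)
        if d is None or not (labels.min() <= d <= labels.max()):
            raise GenerationError(
                f"segment {sid}: true depth {d} um outside the scanned range "
                f"[{labels.min()}, {labels.max()}] um"
            )
    m = int(math.ceil(math.sqrt(len(segment_ids))))
    side = m * cell_px
    stack = config.depth_background + rng.normal(
        0.0, config.depth_noise_sd, (len(labels), side, side)
    )
    masks = {}
    pad = (cell_px - roi_px) // 2
    for k, sid in enumerate(segment_ids):
        r0 = (k // m) * cell_px + pad
        c0 = (k % m) * cell_px + pad
        mask = np.zeros((side, side), dtype=bool)
        mask[r0 : r0 + roi_px, c0 : c0 + roi_px] = True
        masks[sid] = mask
        bell = config.depth_signal_amplitude * np.exp(
            -((labels - truth.depth[sid]) ** 2) / (2.0 * config.depth_sigma**2)
        )
        stack[:, r0 : r0 + roi_px, c0 : c0 + roi_px] += bell[:, None, None]
    return DepthStack(slabs=stack, depth_labels=labels, slab_thickness=config.slab_thickness), masks


# ---------------------------------------------------------------------------
# straightened "division" vessel image
# ---------------------------------------------------------------------------


def generate_division_image(
    true_diameter: float,
    length_px: int = 200,
    px_size: float = 0.5,
    blur_sd: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StraightenedVessel:
    """Straightened vessel image: a bright band of width *true_diameter* um
    centred on the middle column, Gaussian-blurred, plus pixel noise.

    Pixel values are the blurred band's coverage of each pixel (1 inside,
    0 outside for zero blur), so an unblurred integer-pixel diameter yields
    an exactly *diameter/px_size*-pixel-wide band in every row.
    """
    if true_diameter <= 0 or px_size <= 0:
        raise GenerationError("true_diameter and px_size must be > 0")
    if true_diameter < px_size:
        raise GenerationError(
            f"diameter {true_diameter} um is smaller than one pixel ({px_size} um)"
        )
    rng = np.random.default_rng([3, seed])
    margin_px = int(math.ceil((4.0 * max(blur_sd, px_size)) / px_size)) + 6
    width = int(math.ceil(true_diameter / px_size)) + 2 * margin_px
    k = true_diameter / px_size
    if abs(k - round(k)) < 1e-9:
        # align pixel boundaries with the band edges for integer-pixel widths
        if (round(k) % 2 == 0) != (width % 2 == 0):
            width += 1
    center = (width - 1) / 2.0
    u = (np.arange(width) - center) * px_size
    sigma = max(blur_sd, 1e-9)
    cov_hi = _blurred_band_cdf_integral(u + px_size / 2.0, true_diameter / 2.0, sigma)
    cov_lo = _blurred_band_cdf_integral(u - px_size / 2.0, true_diameter / 2.0, sigma)
    profile = np.clip((cov_hi - cov_lo) / px_size, 0.0, 1.0)
    # snap float residue so an unblurred band is exactly binary
    profile[profile > 1.0 - 1e-9] = 1.0
    profile[profile < 1e-9] = 0.0
    image = np.tile(profile, (length_px, 1))
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, image.shape)
    return StraightenedVessel(image=image, px_size=px_size, centerline_col=center)


# ---------------------------------------------------------------------------
# writers (plain-text CSV / JSON, TIFF for image stacks)
# ---------------------------------------------------------------------------


def write_network_csv(net, truth, segments_path, edges_path) -> None:
    seg_df, edge_df = network_tables(net, truth)
    seg_df.to_csv(segments_path, index=False)
    edge_df.to_csv(edges_path, index=False)


def write_traces_csv(traces: dict, path) -> None:
    """One column per segment (header = id), first column = time in s."""
    sids = sorted(traces)
    rate = traces[sids[0]].rate
    n = traces[sids[0]].samples.size
    out = {"time_s": np.arange(n) / rate}
    for sid in sids:
        out[sid] = traces[sid].samples
    pd.DataFrame(out).to_csv(path, index=False)


def write_depth_stack(stack, path, sidecar_path=None) -> None:
    """Multi-page TIFF, one page per slab in increasing depth, plus a JSON
    sidecar with the depth labels."""
    tifffile.imwrite(path, stack.slabs.astype(np.float32))
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "depth_labels_um": list(map(float, stack.depth_labels)),
                    "slab_thickness_um": stack.slab_thickness,
                },
                fh,
                indent=1,
            )


def write_masks(masks: dict, path, sidecar_path=None) -> None:
    """Integer label image (0 = background); label i+1 = i-th sorted vessel."""
    sids = sorted(masks)
    shape = masks[sids[0]].shape
    label = np.zeros(shape, dtype=np.int32)
    for i, sid in enumerate(sids):
        label[masks[sid]] = i + 1
    tifffile.imwrite(path, label)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"labels": {sid: i + 1 for i, sid in enumerate(sids)}}, fh, indent=1)


def read_depth_stack(path, sidecar_path):
    from .depth_profiles import DepthStack

    arr = tifffile.imread(path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return DepthStack(
        slabs=np.asarray(arr, dtype=float),
        depth_labels=np.asarray(meta["depth_labels_um"], dtype=float),
        slab_thickness=float(meta.get("slab_thickness_um", 40.0)),
    )


def read_masks(path, sidecar_path) -> dict:
    label = tifffile.imread(path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return {sid: label == lab for sid, lab in meta["labels"].items()}


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "exponents": truth.exponents,
        "diameter_um": truth.diameter,
        "depth_um": truth.depth,
        "branch_order": truth.branch_order,
        "feeder_distance_um": truth.feeder_distance,
        "capillary_type": truth.capillary_type,
        "je_upstream": truth.je_upstream,
        "je_downstream": truth.je_downstream,
        "flow": truth.flow,
        "voi_ids": truth.voi_ids,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
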