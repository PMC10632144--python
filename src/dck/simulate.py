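"""Synthetic fixtures with the statistical structure the analyses assume.

Three generators, each fully determined by a config and its seed:

- :func:`synth_connectome` plants USN clusters with known exclusive or
  shared connectivity onto a DAN catalog with the standard per-type member
  counts (8, 15, 10, 26, 5, 19, 3; 86 DANs in total), log-normal synapse
  weights, excluded-category distractor neurons and optional weak
  background ("noise") edges, and returns a ground-truth manifest for
  recovery tests.
- :func:`synth_traces` builds two-channel (indicator + reference) ROI
  traces with a planted double-exponential response kernel, per-trial
  adaptation, a multiplicative motion artifact shared by both channels,
  and additive acquisition noise.
- :func:`synth_arm_counts` draws binomial T-maze arm counts at a known
  approach probability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import ArmCounts
from .connectome import DAN_TYPE_INFO, FLAG_TYPE
from .imaging import DEFAULT_FRAME_RATE, RoiTraceSet, StimulusEvent

# ---------------------------------------------------------------------------
# Connectome generator
# ---------------------------------------------------------------------------

#: specificity class -> compartment groups the class's clusters innervate
CLASS_GROUPS: dict[str, tuple[str, ...]] = {
    "bp2": ("bp2",),
    "g4": ("g4",),
    "g5": ("g5",),
    "bp2+g4": ("bp2", "g4"),
    "bp2+g4+g5": ("bp2", "g4", "g5"),
}

#: compartment group -> member DAN types (generator-side copy)
GROUP_TYPES: dict[str, tuple[str, ...]] = {
    "bp2": ("PAM02", "PAM06", "PAM05"),
    "g4": ("PAM08",),
    "g5": ("PAM01", "PAM15"),
}

DISTRACTOR_LABELS = (
    "KCg-m", "KCab-s", "KCa'b'-m", "PAM04_a", "PAM10_b", "PPL101", "PPL102",
    "APL", "DPM", "MBON05", "MBON09", "MBON11",
)


@dataclass(frozen=True)
class ConnectomeSimConfig:
    """Study conditions for the planted connectome.

    Cluster counts per specificity class default to the class tallies of
    the reference input map (40 beta'2-exclusive, 8 gamma4, 33 gamma5,
    10 shared beta'2+gamma4 only, 14 shared by all three compartments).
    Synapse weights are log-normal (median ~12 synapses); planted
    cluster-to-DAN edges are guaranteed to stay above ``guard_percent`` of
    the DAN's total input so the planted structure survives the display
    threshold. ``noise_edge_prob`` is the per-(USN, non-assigned DAN)
    probability of a weak spurious edge (1-2 synapses).
    """

    dan_counts: Mapping[str, int] = field(
        default_factory=lambda: {t: n for t, (_, _, n) in DAN_TYPE_INFO.items()}
    )
    n_clusters: Mapping[str, int] = field(
        default_factory=lambda: {"bp2": 40, "g4": 8, "g5": 33, "bp2+g4": 10, "bp2+g4+g5": 14}
    )
    cluster_size_range: tuple[int, int] = (1, 34)
    size_geom_p: float = 0.45
    syn_lognorm_mu: float = 2.5
    syn_lognorm_sigma: float = 0.8
    coverage_range: tuple[float, float] = (0.25, 1.0)
    guard_percent: float = 0.8
    p_flag_type: float = 0.1
    n_distractors: int = 24
    n_axonal_only: int = 3
    n_dan_dan_edges: int = 10
    noise_edge_prob: float = 0.01
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["dan_counts"] = dict(d["dan_counts"])
        d["n_clusters"] = dict(d["n_clusters"])
        return json.dumps(d, indent=2, sort_keys=True)


def _cluster_sizes(rng: np.random.Generator, n: int, cfg: ConnectomeSimConfig) -> np.ndarray:
    lo, hi = cfg.cluster_size_range
    sizes = lo - 1 + rng.geometric(cfg.size_geom_p, size=n)
    return np.clip(sizes, lo, hi)


def synth_connectome(
    cfg: ConnectomeSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (neurons, edges, truth) tables for a planted connectome.

    Every planted cluster covers at least 20% of the members of each DAN
    type in its assigned compartment groups, with synapse weights strong
    enough that the cluster-level percentage input exceeds the guard level
    after normalisation. The truth manifest records DAN ids per type,
    planted USN ids and per-cluster membership, groups and class labels.
    """
    cfg = cfg or ConnectomeSimConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- DANs -------------------------------------------------------------
    dan_rows, dan_ids_by_type = [], {}
    next_id = 1000
    for t, count in cfg.dan_counts.items():
        ids = []
        for k in range(count):
            ids.append(next_id)
            dan_rows.append(
                {
                    "neuron_id": next_id,
                    "type_label": f"{t}_{chr(ord('a') + k % 5)}",
                    "category": "target_dan",
                    "hemisphere": "right",
                    "sez_associated": False,
                }
            )
            next_id += 1
        dan_ids_by_type[t] = ids
    all_dans = [i for ids in dan_ids_by_type.values() for i in ids]

    # --- planted clusters and coverage ------------------------------------
    labels = [cls for cls, n in cfg.n_clusters.items() for _ in range(n)]
    sizes = _cluster_sizes(rng, len(labels), cfg)
    usn_rows, clusters = [], []
    next_usn = 20000
    for idx, (cls, size) in enumerate(zip(labels, sizes)):
        type_label = f"U{idx:03d}"
        members = list(range(next_usn, next_usn + int(size)))
        next_usn += int(size)
        for m in members:
            usn_rows.append(
                {
                    "neuron_id": m,
                    "type_label": type_label,
                    "category": "candidate_usn",
                    "hemisphere": "right",
                    "sez_associated": False,
                }
            )
        groups = CLASS_GROUPS[cls]
        types = [t for g in groups for t in GROUP_TYPES[g]]
        flagged = bool(rng.random() < cfg.p_flag_type)
        if flagged:
            types = types + [FLAG_TYPE]
        covered: dict[str, list[int]] = {}
        for t in types:
            pool = dan_ids_by_type[t]
            f = rng.uniform(*cfg.coverage_range)
            n_cov = max(math.ceil(0.2 * len(pool)), math.ceil(f * len(pool)))
            covered[t] = sorted(rng.choice(pool, size=n_cov, replace=False).tolist())
        clusters.append(
            {
                "cluster_id": type_label,
                "members": members,
                "class": cls,
                "groups": list(groups),
                "flag_type": flagged,
                "covered": covered,
            }
        )
    if next_usn == 20000:
        raise ValueError("infeasible config: no USN clusters requested")

    # --- planted weights ---------------------------------------------------
    # weights[(usn, dan)] -> float synapse weight
    weights: dict[tuple[int, int], float] = {}
    pair_cluster: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for c in clusters:
        for t, dans in c["covered"].items():
            for d in dans:
                keys = []
                for m in c["members"]:
                    w = float(rng.lognormal(cfg.syn_lognorm_mu, cfg.syn_lognorm_sigma))
                    weights[(m, d)] = weights.get((m, d), 0.0) + w
                    keys.append((m, d))
                pair_cluster.setdefault((c["cluster_id"], d), []).extend(keys)

    # --- enforce the guard: planted cluster edges stay above guard_percent -
    # Weights are keyed per (USN, DAN), so each DAN's percentages are
    # independent of every other DAN and the floor can be solved per DAN in
    # closed form: clusters below the floor are raised to exactly the floor
    # share of the new total, diluting the rest; the below-floor set grows
    # monotonically, so the loop is bounded by the number of covering
    # clusters.
    f = cfg.guard_percent / 100.0
    by_dan: dict[int, list[tuple[str, list[tuple[int, int]]]]] = {}
    for (cid, d), keys in pair_cluster.items():
        by_dan.setdefault(d, []).append((cid, keys))
    for d, covering in by_dan.items():
        wc = {cid: sum(weights[k] for k in keys) for cid, keys in covering}
        S = sum(wc.values())
        floored: set[str] = set()
        for _ in range(len(covering) + 1):
            kept = sum(w for cid, w in wc.items() if cid not in floored)
            if len(floored) * f >= 1.0:
                raise ValueError(
                    "infeasible config: too many clusters share one DAN for the guard level"
                )
            S_new = kept / (1.0 - len(floored) * f)
            fresh = {
                cid
                for cid, w in wc.items()
                if cid not in floored and w / S_new < f * (1.0 - 1e-12)
            }
            if not fresh:
                S = S_new
                break
            floored |= fresh
        for cid, keys in covering:
            if cid in floored:
                scale = (f * S) / wc[cid]
                for k in keys:
                    weights[k] *= scale

    edge_rows = [
        {
            "pre_id": u,
            "post_id": d,
            "synapse_count": max(1, int(round(w))),
            "post_site_class": "dendritic",
        }
        for (u, d), w in sorted(weights.items())
    ]

    # --- background noise edges -------------------------------------------
    if cfg.noise_edge_prob > 0:
        planted_pairs = set(weights)
        usn_ids = [r["neuron_id"] for r in usn_rows]
        for u in usn_ids:
            hits = np.flatnonzero(rng.random(len(all_dans)) < cfg.noise_edge_prob)
            for j in hits:
                d = all_dans[j]
                if (u, d) in planted_pairs:
                    continue
                edge_rows.append(
                    {
                        "pre_id": u,
                        "post_id": d,
                        "synapse_count": int(rng.integers(1, 3)),
                        "post_site_class": "unknown",
                    }
                )

    # --- excluded distractors, axonal-only neurons, DAN-DAN edges ----------
    extra_rows = []
    next_x = 90000
    for k in range(cfg.n_distractors):
        label = DISTRACTOR_LABELS[k % len(DISTRACTOR_LABELS)]
        extra_rows.append(
            {
                "neuron_id": next_x,
                "type_label": label,
                "category": "excluded",
                "hemisphere": "right",
                "sez_associated": False,
            }
        )
        for d in rng.choice(all_dans, size=int(rng.integers(3, 11)), replace=False):
            edge_rows.append(
                {
                    "pre_id": next_x,
                    "post_id": int(d),
                    "synapse_count": max(1, int(rng.lognormal(cfg.syn_lognorm_mu, cfg.syn_lognorm_sigma))),
                    "post_site_class": "dendritic",
                }
            )
        next_x += 1
    for k in range(cfg.n_axonal_only):
        extra_rows.append(
            {
                "neuron_id": next_x,
                "type_label": f"AXO{k}",
                "category": "candidate_usn",
                "hemisphere": "right",
                "sez_associated": False,
            }
        )
        for d in rng.choice(all_dans, size=3, replace=False):
            edge_rows.append(
                {
                    "pre_id": next_x,
                    "post_id": int(d),
                    "synapse_count": int(rng.integers(5, 20)),
                    "post_site_class": "axonal",
                }
            )
        next_x += 1
    for _ in range(cfg.n_dan_dan_edges):
        a, b = rng.choice(all_dans, size=2, replace=False)
        edge_rows.append(
            {
                "pre_id": int(a),
                "post_id": int(b),
                "synapse_count": int(rng.integers(1, 6)),
                "post_site_class": "dendritic",
            }
        )

    neurons = pd.DataFrame(dan_rows + usn_rows + extra_rows)
    edges = pd.DataFrame(edge_rows)
    truth = {
        "dan_ids": dan_ids_by_type,
        "usn_ids": sorted(r["neuron_id"] for r in usn_rows),
        "clusters": [
            {k: v for k, v in c.items() if k != "covered"} for c in clusters
        ],
        "config": json.loads(cfg.to_json()),
    }
    return neurons, edges, truth


def class_recovery(calls: pd.DataFrame, truth: dict, *, check_flag: bool = False) -> float:
    """Fraction of planted clusters whose specificity class is recovered.

    A cluster counts as recovered when the set of connected compartment
    groups in ``calls`` equals its planted groups; with ``check_flag`` the
    gamma4<gamma1gamma2 flag must match as well.
    """
    truth_by_id = {c["cluster_id"]: c for c in truth["clusters"]}
    ix = calls.set_index("cluster_id")
    ok = 0
    for cid, tc in truth_by_id.items():
        if cid not in ix.index:
            continue
        row = ix.loc[cid]
        got = {g for g in GROUP_TYPES if bool(row[g])}
        hit = got == set(tc["groups"])
        if check_flag:
            hit = hit and bool(row["gamma4g1g2_flag"]) == bool(tc["flag_type"])
        ok += int(hit)
    return ok / len(truth_by_id)


# ---------------------------------------------------------------------------
# Two-channel trace generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceSimConfig:
    """Study conditions for synthetic ratiometric traces.

    The response kernel is a double exponential normalised to unit peak,
    scaled by ``amplitude`` times the physiological-state multiplier and
    the per-trial adaptation factor rho**k. The motion artifact is a slow
    multiplicative oscillation applied identically to both channels, so a
    perfect ratio cancels it.
    """

    frame_rate: float = DEFAULT_FRAME_RATE
    baseline_signal: float = 100.0
    baseline_reference: float = 50.0
    tau_rise_s: float = 0.5
    tau_decay_s: float = 2.0
    amplitude: float = 1.0
    state_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"starved": 1.5, "dehydrated": 1.2, "satiated": 1.0}
    )
    rho: float = 0.8
    artifact_amplitude: float = 0.1
    artifact_freq_hz: float = 0.3
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError("adaptation factor rho must lie in (0, 1]")
        if self.amplitude < 0 or self.artifact_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("amplitudes and noise must be non-negative")


def kernel_peak_time(tau_rise_s: float, tau_decay_s: float) -> float:
    """Analytic peak time of the unit double-exponential kernel."""
    return (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)) * math.log(
        tau_decay_s / tau_rise_s
    )


def _kernel(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    """Double-exponential kernel normalised to unit peak (zero for t < 0)."""
    tt = np.maximum(t, 0.0)
    raw = (np.exp(-tt / tau_d) - np.exp(-tt / tau_r)) * (t >= 0)
    tp = kernel_peak_time(tau_r, tau_d)
    norm = math.exp(-tp / tau_d) - math.exp(-tp / tau_r)
    return raw / norm


def synth_traces(
    cfg: TraceSimConfig,
    events: Sequence[StimulusEvent],
    *,
    state: str = "satiated",
    total_s: float | None = None,
    roi: str = "g5n",
) -> dict[str, RoiTraceSet]:
    """Two-channel traces for both hemispheres with a planted response.

    signal = baseline * (1 + response) * artifact + noise and
    reference = baseline * artifact + noise, with the artifact shared
    between channels and hemispheres. The response to trial k (0-based,
    within each modality) is the unit kernel scaled by
    amplitude * state multiplier * rho**k.
    """
    if total_s is None:
        total_s = max(e.onset + e.duration for e in events) + 30.0
    n = int(round(total_s * cfg.frame_rate))
    t = np.arange(n) / cfg.frame_rate
    mult = cfg.state_multipliers.get(state, 1.0)
    resp = np.zeros(n)
    order: dict[str, int] = {}
    for e in sorted(events, key=lambda e: e.onset):
        k = order.get(e.modality, 0)
        order[e.modality] = k + 1
        amp = cfg.amplitude * mult * cfg.rho**k
        resp += amp * _kernel(t - e.onset, cfg.tau_rise_s, cfg.tau_decay_s)
    artifact = 1.0 + cfg.artifact_amplitude * np.sin(
        2 * np.pi * cfg.artifact_freq_hz * t
    )
    rng = np.random.default_rng(cfg.seed)
    out = {}
    for hemi in ("left", "right"):
        sig = cfg.baseline_signal * (1.0 + resp) * artifact
        ref = cfg.baseline_reference * artifact
        if cfg.noise_sigma > 0:
            sig = sig + rng.normal(0.0, cfg.noise_sigma, n)
            ref = ref + rng.normal(0.0, cfg.noise_sigma, n)
        out[hemi] = RoiTraceSet(
            roi=roi, hemisphere=hemi, signal=sig, reference=ref, frame_rate=cfg.frame_rate
        )
    return out


def traces_to_table(traces: Mapping[str, RoiTraceSet], fly_id: int = 1) -> pd.DataFrame:
    """Long-form trace table (fly_id, roi, hemisphere, channel, frame_index, value)."""
    rows = []
    for hemi, ts in traces.items():
        for channel, arr in (("signal", ts.signal), ("reference", ts.reference)):
            rows.append(
                pd.DataFrame(
                    {
                        "fly_id": fly_id,
                        "roi": ts.roi,
                        "hemisphere": hemi,
                        "channel": channel,
                        "frame_index": np.arange(len(arr)),
                        "value": arr,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Arm counts
# ---------------------------------------------------------------------------


def synth_arm_counts(p_true: float, n: int, seed: int = 0) -> ArmCounts:
    """Binomial T-maze arm counts at a known approach probability."""
    if not 0 <= p_true <= 1:
        raise ValueError("p_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_target = int(rng.binomial(n, p_true))
    return ArmCounts(n_target=n_target, n_other=n - n_target)
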