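"""Upstream-input mapping of mushroom-body reward dopaminergic neurons (DANs).

Given a synaptic edge table and a neuron annotation table from a dense
connectome export, this module identifies the upstream neurons (USNs) that
provide direct dendritic input to a catalog of targeted PAM DAN types, and
computes each USN's *percentage dendritic input*: its synapse count onto a
DAN divided by that DAN's total dendritic input from all included USNs,
times 100.

Intrinsic mushroom-body neurons and modulatory cell classes that synapse
within the lobes but are not considered upstream partners (Kenyon cells,
PAM and PPL DANs, APL, DPM, and the three axo-axonal MBONs) are excluded
both from the USN set and from the normalising denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dck")

# ---------------------------------------------------------------------------
# DAN type catalog
# ---------------------------------------------------------------------------

#: type code -> (compartment subtype, exclusivity group or None, member count)
#: The exclusivity group is the horizontal-lobe compartment used for
#: specificity calls; the gamma4<gamma1gamma2 type (PAM07) is tracked as a
#: separate flag rather than a group of its own.
DAN_TYPE_INFO: dict[str, tuple[str, str | None, int]] = {
    "PAM02": ("bp2a", "bp2", 8),
    "PAM06": ("bp2m", "bp2", 15),
    "PAM05": ("bp2p", "bp2", 10),
    "PAM08": ("g4", "g4", 26),
    "PAM07": ("g4_g1g2", None, 5),
    "PAM01": ("g5", "g5", 19),
    "PAM15": ("g5bp2a", "g5", 3),
}

#: compartment group -> type codes counted toward it for exclusivity calls
COMPARTMENT_GROUPS: dict[str, tuple[str, ...]] = {
    "bp2": ("PAM02", "PAM06", "PAM05"),
    "g4": ("PAM08",),
    "g5": ("PAM01", "PAM15"),
}

#: type whose connectivity is recorded as a separate flag
FLAG_TYPE = "PAM07"

#: named DAN type selections used for cluster ranking
SELECTIONS: dict[str, tuple[str, ...]] = {
    "all7": tuple(DAN_TYPE_INFO),
    "b2g4": ("PAM02", "PAM06", "PAM05", "PAM08"),
}


@dataclass(frozen=True)
class DanTypeCatalog:
    """The targeted PAM DAN types and their member neuron ids.

    ``members`` maps a type code (e.g. ``"PAM08"``) to a tuple of neuron
    ids; membership is resolved from the annotation table by type-label
    prefix (``PAM08_a`` belongs to ``PAM08``).
    """

    members: Mapping[str, tuple[int, ...]]

    @property
    def type_codes(self) -> tuple[str, ...]:
        return tuple(self.members)

    @property
    def dan_ids(self) -> frozenset[int]:
        return frozenset(i for ids in self.members.values() for i in ids)

    @property
    def total(self) -> int:
        return sum(len(ids) for ids in self.members.values())

    def member_count(self, type_code: str) -> int:
        return len(self.members[type_code])

    def type_of(self) -> dict[int, str]:
        """Map neuron id -> DAN type code."""
        return {i: t for t, ids in self.members.items() for i in ids}

    @classmethod
    def from_neurons(
        cls, neurons: pd.DataFrame, type_codes: Iterable[str] = tuple(DAN_TYPE_INFO)
    ) -> "DanTypeCatalog":
        """Build the catalog from an annotation table by type-label prefix."""
        _check_neurons(neurons)
        members: dict[str, tuple[int, ...]] = {}
        labels = neurons["type_label"].astype(str)
        for code in type_codes:
            hit = labels.str.startswith(code)
            members[code] = tuple(sorted(neurons.loc[hit, "neuron_id"].astype(int)))
        if sum(len(v) for v in members.values()) == 0:
            raise ValueError("catalog is empty: no neuron matches any DAN type code")
        return cls(members=members)


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

DEFAULT_EXCLUSION_PATTERNS: tuple[str, ...] = (
    "KC",       # Kenyon cells
    "PAM",      # all PAM DANs, target or not
    "PPL",      # PPL DANs
    "APL",      # anterior paired lateral
    "DPM",      # dorsal paired medial
    "MBON05",   # axo-axonal MBONs
    "MBON09",
    "MBON11",
)


@dataclass(frozen=True)
class ExclusionRules:
    """Type-label prefix patterns whose neurons are never counted as USNs."""

    patterns: tuple[str, ...] = DEFAULT_EXCLUSION_PATTERNS

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("exclusion pattern list must be non-empty")

    def matches(self, type_label: str) -> bool:
        return any(str(type_label).startswith(p) for p in self.patterns)

    def mask(self, labels: pd.Series) -> pd.Series:
        s = labels.astype(str)
        out = pd.Series(False, index=s.index)
        for p in self.patterns:
            out |= s.str.startswith(p)
        return out


# ---------------------------------------------------------------------------
# Table validation and I/O
# ---------------------------------------------------------------------------

NEURON_COLUMNS = ("neuron_id", "type_label", "category", "hemisphere", "sez_associated")
EDGE_COLUMNS = ("pre_id", "post_id", "synapse_count")


def _check_neurons(neurons: pd.DataFrame) -> None:
    missing = [c for c in NEURON_COLUMNS[:2] if c not in neurons.columns]
    if missing:
        raise ValueError(f"neuron table lacks required columns: {missing}")
    if neurons["neuron_id"].duplicated().any():
        dup = neurons.loc[neurons["neuron_id"].duplicated(), "neuron_id"].iloc[0]
        raise ValueError(f"duplicate neuron_id in annotation table: {dup}")


def _check_edges(edges: pd.DataFrame) -> None:
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table lacks required columns: {missing}")
    if (edges["synapse_count"] < 0).any():
        raise ValueError("negative synapse_count in edge table")


def load_neurons(path) -> pd.DataFrame:
    """Read a neuron annotation table (comma- or tab-separated, header row)."""
    df = pd.read_csv(path, sep=None, engine="python")
    _check_neurons(df)
    if "sez_associated" in df.columns:
        df["sez_associated"] = df["sez_associated"].astype(bool)
    return df


def load_edges(path) -> pd.DataFrame:
    """Read a synapse edge table; ``post_site_class`` defaults to unknown."""
    df = pd.read_csv(path, sep=None, engine="python")
    _check_edges(df)
    if "post_site_class" not in df.columns:
        df["post_site_class"] = "unknown"
    return df


def _clean_edges(edges: pd.DataFrame, dendritic_only: bool) -> pd.DataFrame:
    """Drop self-loops and non-dendritic postsynaptic sites."""
    if "post_site_class" in edges.columns:
        cls = edges["post_site_class"].fillna("unknown").astype(str)
    else:
        cls = pd.Series("unknown", index=edges.index)
    keep = cls == "dendritic"
    if not dendritic_only:
        keep |= cls == "unknown"
    keep &= edges["pre_id"] != edges["post_id"]
    keep &= edges["synapse_count"] > 0
    return edges.loc[keep]


# ---------------------------------------------------------------------------
# USN identification
# ---------------------------------------------------------------------------

def identify_usns(
    edges: pd.DataFrame,
    neurons: pd.DataFrame,
    catalog: DanTypeCatalog,
    rules: ExclusionRules | None = None,
    *,
    dendritic_only: bool = False,
) -> set[int]:
    """Identify upstream neurons of the catalog DANs.

    A USN is any annotated neuron with at least one dendritic synapse onto
    any catalog DAN, excluding neurons whose type label matches an
    exclusion pattern and excluding the catalog DANs themselves. Edges
    whose postsynaptic site class is ``unknown`` count as dendritic unless
    ``dendritic_only`` is set.
    """
    rules = rules or ExclusionRules()
    _check_neurons(neurons)
    if len(edges):
        _check_edges(edges)
    if catalog.total == 0:
        raise ValueError("empty DAN type catalog")
    if len(edges) == 0:
        return set()

    known = set(neurons["neuron_id"].astype(int))
    endpoints = set(edges["pre_id"].astype(int)) | set(edges["post_id"].astype(int))
    stray = endpoints - known
    if stray:
        raise ValueError(f"edge references unannotated neuron id {min(stray)}")

    dan_ids = catalog.dan_ids
    ed = _clean_edges(edges, dendritic_only)
    ed = ed.loc[ed["post_id"].isin(dan_ids)]
    candidates = set(ed["pre_id"].astype(int)) - set(dan_ids)

    labels = neurons.set_index("neuron_id")["type_label"].fillna("")
    excluded = {i for i in candidates if rules.matches(labels.get(i, ""))}
    usns = candidates - excluded

    n_blank = sum(1 for i in usns if str(labels.get(i, "")) == "")
    if n_blank:
        logger.info("retained %d candidate USNs with empty type labels", n_blank)
    return usns


def percent_dendritic_input(
    edges: pd.DataFrame,
    dan_id: int,
    usns: set[int],
    *,
    dendritic_only: bool = False,
) -> pd.DataFrame:
    """Percentage dendritic input from each USN onto one DAN.

    The denominator is the DAN's total dendritic input from the included
    USNs only (previously excluded neurons do not contribute). Returns a
    frame with columns (usn_id, dan_id, percent); empty, with a logged
    warning, for a DAN with no included input.
    """
    ed = _clean_edges(edges, dendritic_only)
    ed = ed.loc[(ed["post_id"] == dan_id) & ed["pre_id"].isin(usns)]
    syn = ed.groupby("pre_id")["synapse_count"].sum()
    total = syn.sum()
    if total == 0:
        logger.warning("DAN %s has no included dendritic input", dan_id)
        return pd.DataFrame(columns=["usn_id", "dan_id", "percent"])
    out = pd.DataFrame(
        {
            "usn_id": syn.index.astype(int),
            "dan_id": dan_id,
            "percent": 100.0 * syn.to_numpy(dtype=float) / float(total),
        }
    )
    return out.sort_values("usn_id", ignore_index=True)


def input_fractions(
    edges: pd.DataFrame,
    catalog: DanTypeCatalog,
    usns: set[int],
    *,
    dendritic_only: bool = False,
) -> pd.DataFrame:
    """Percentage dendritic input for every catalog DAN, as one long table.

    Columns: usn_id, dan_id, dan_type, percent. Fractions for each DAN sum
    to 100 whenever the DAN has at least one included input.
    """
    type_of = catalog.type_of()
    parts = []
    for dan_id in sorted(catalog.dan_ids):
        f = percent_dendritic_input(edges, dan_id, usns, dendritic_only=dendritic_only)
        if len(f):
            f = f.assign(dan_type=type_of[dan_id])
            parts.append(f)
    if not parts:
        return pd.DataFrame(columns=["usn_id", "dan_id", "dan_type", "percent"])
    return pd.concat(parts, ignore_index=True)[["usn_id", "dan_id", "dan_type", "percent"]]


def convergence_ratio(n_usns: int, n_dans: int) -> float:
    """Fan-in convergence of neuron number: upstream count per target count."""
    if n_dans <= 0:
        raise ValueError("n_dans must be positive")
    return n_usns / n_dans
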