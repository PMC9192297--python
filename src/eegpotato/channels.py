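"""Region-based channel selection for the 18-channel bipolar montage.

Nearby bipolar derivations are highly redundant (Pearson correlation of
adjacent channels routinely exceeds 0.5), so the scalp is partitioned
into nine regions of two channels each and one channel per region is
kept — both for the central region (FZCZ, CZPZ), which sits closest to
deep sources and carries the least noise.  Within the other regions the
pick is driven by mean power spectral density: epochs with epileptiform
activity show elevated PSD, so the channel with clearly larger mean PSD
in *both* conditions (seizure and non-seizure) wins; when neither
channel dominates, the candidate farthest on the scalp from the
already-selected channels is taken, maximizing spatial coverage.

The module ships the published per-record mean-PSD and channel-
correlation summary tables for six CHB-MIT records (chb01_03, chb01_04,
chb03_01, chb03_02, chb05_13, chb05_16), from which the standard
10-channel subset is reproduced, and that subset as a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MONTAGE18, _montage_split

__all__ = [
    "RegionMap",
    "PSDTable",
    "CorrTable",
    "default_region_map",
    "electrode_coords_1020",
    "channel_position",
    "correlated_pairs",
    "region_winner",
    "farthest_channel",
    "select_channels",
    "SELECTED_CHANNELS_10",
    "chb_psd_table",
    "chb_corr_table",
]

#: The standard 10-channel subset produced by the selection procedure on
#: the shipped CHB-MIT summary tables, in montage order.
SELECTED_CHANNELS_10: tuple[str, ...] = (
    "F7T7", "T7P7", "FP1F3", "P3O1", "FP2F4",
    "P4O2", "F8T8", "T8P8", "FZCZ", "CZPZ",
)

CONDITIONS = ("epilepsy", "nonepilepsy")


@dataclass(frozen=True)
class RegionMap:
    """Nine disjoint two-channel scalp regions covering the montage."""

    regions: dict[str, tuple[str, str]]
    central: str = "central"

    def __post_init__(self) -> None:
        all_ch = [c for pair in self.regions.values() for c in pair]
        if len(self.regions) != 9:
            raise ValueError("expected exactly 9 regions")
        if sorted(all_ch) != sorted(MONTAGE18):
            raise ValueError("regions must partition the 18-channel montage")
        if self.central not in self.regions:
            raise ValueError(f"central region {self.central!r} missing")

    def items(self):
        return self.regions.items()


def default_region_map() -> RegionMap:
    """The standard pairing of the 18 montage channels into 9 regions."""
    return RegionMap(regions={
        "region1": ("FP1F7", "FP1F3"),
        "region2": ("F7T7", "F3C3"),
        "region3": ("T7P7", "C3P3"),
        "region4": ("P7O1", "P3O1"),
        "region5": ("FP2F4", "FP2F8"),
        "region6": ("F4C4", "F8T8"),
        "region7": ("C4P4", "T8P8"),
        "region8": ("P4O2", "P8O2"),
        "central": ("FZCZ", "CZPZ"),
    })


# ---------------------------------------------------------------------------
# tables

@dataclass
class PSDTable:
    """Mean PSD per (channel, record, condition).

    Backed by a DataFrame with columns channel, record, condition, value;
    conditions are "epilepsy" and "nonepilepsy".
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"channel", "record", "condition", "value"}
        if not required <= set(self.df.columns):
            raise ValueError(f"PSDTable needs columns {sorted(required)}")

    def channel_mean(self, channel: str, condition: str) -> float:
        sel = self.df[(self.df.channel == channel) & (self.df.condition == condition)]
        if sel.empty:
            raise KeyError(f"no PSD rows for ({channel}, {condition})")
        return float(sel.value.mean())

    def records(self, channel: str, condition: str) -> set[str]:
        sel = self.df[(self.df.channel == channel) & (self.df.condition == condition)]
        return set(sel.record)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PSDTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class CorrTable:
    """Pairwise channel Pearson correlations per condition.

    Columns channel_a, channel_b, condition, rho; the pair is unordered
    (lookups are symmetric in a/b).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"channel_a", "channel_b", "condition", "rho"}
        if not required <= set(self.df.columns):
            raise ValueError(f"CorrTable needs columns {sorted(required)}")
        if (self.df.rho.abs() > 1 + 1e-12).any():
            raise ValueError("|rho| must not exceed 1")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def correlated_pairs(
    corr: CorrTable, threshold: float = 0.5, condition: str = "epilepsy"
) -> list[tuple[str, str, float]]:
    """Channel pairs whose correlation reaches *threshold* in *condition*.

    Rows with rho >= threshold, sorted descending by rho.  The pair order
    within a row is as stored; lookups treat (a, b) and (b, a) alike.
    """
    sel = corr.df[(corr.df.condition == condition) & (corr.df.rho >= threshold)]
    sel = sel.sort_values("rho", ascending=False, kind="stable")
    return [(r.channel_a, r.channel_b, float(r.rho)) for r in sel.itertuples()]


# ---------------------------------------------------------------------------
# scalp geometry

def electrode_coords_1020() -> dict[str, tuple[float, float]]:
    """Schematic 2-D positions of the 10-20 electrodes used by the montage.

    Outer-ring electrodes sit on the unit circle at the standard angles;
    the inner frontal/central/parietal grid at ±0.5.  x grows to the
    right, y to the front.
    """
    c18, c54 = np.cos(np.deg2rad(18)), np.cos(np.deg2rad(54))
    s18, s54 = np.sin(np.deg2rad(18)), np.sin(np.deg2rad(54))
    return {
        "FP1": (-s18, c18), "FP2": (s18, c18),   # 108 and 72 degrees
        "F7": (-s54, c54), "F8": (s54, c54),     # 144 and 36 degrees
        "T7": (-1.0, 0.0), "T8": (1.0, 0.0),
        "P7": (-s54, -c54), "P8": (s54, -c54),
        "O1": (-s18, -c18), "O2": (s18, -c18),
        "F3": (-0.5, 0.5), "F4": (0.5, 0.5),
        "C3": (-0.5, 0.0), "C4": (0.5, 0.0),
        "P3": (-0.5, -0.5), "P4": (0.5, -0.5),
        "FZ": (0.0, 0.5), "CZ": (0.0, 0.0), "PZ": (0.0, -0.5),
    }


def channel_position(
    channel: str, coords: dict[str, tuple[float, float]] | None = None
) -> np.ndarray:
    """2-D scalp position of a bipolar channel: midpoint of its electrodes."""
    coords = coords or electrode_coords_1020()
    e1, e2 = _montage_split(channel)
    p1, p2 = np.array(coords[e1]), np.array(coords[e2])
    return (p1 + p2) / 2.0


# ---------------------------------------------------------------------------
# selection

def region_winner(
    region: tuple[str, str],
    psd: PSDTable,
    rel_margin: float = 0.10,
) -> str | None:
    """PSD-dominant channel of a two-channel region, or None if uncertain.

    Each channel's mean PSD is averaged over records per condition.  A
    channel wins iff it is larger in both conditions and its relative
    excess over the other channel reaches ``rel_margin`` in at least one
    condition; otherwise the comparison is uncertain.
    """
    a, b = region
    for cond in CONDITIONS:
        if psd.records(a, cond) != psd.records(b, cond):
            raise ValueError(
                f"channels {a}/{b} cover different records in {cond}"
            )
    means = {
        ch: {cond: psd.channel_mean(ch, cond) for cond in CONDITIONS}
        for ch in region
    }
    for winner, loser in ((a, b), (b, a)):
        dominant = all(
            means[winner][c] > means[loser][c] for c in CONDITIONS
        )
        by_margin = any(
            means[winner][c] >= (1.0 + rel_margin) * means[loser][c]
            for c in CONDITIONS
        )
        if dominant and by_margin:
            return winner
    return None


def farthest_channel(
    region: tuple[str, str],
    already_selected: set[str] | list[str],
    coords: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Region candidate farthest from the channels already selected.

    Distance of a candidate is its minimum Euclidean scalp distance to
    any already-selected channel (bipolar positions are electrode
    midpoints).  Ties break deterministically by montage order.
    """
    if not already_selected:
        raise ValueError("farthest_channel needs at least one anchor channel")
    coords = coords or electrode_coords_1020()
    anchors = [channel_position(c, coords) for c in already_selected]

    def min_dist(ch: str) -> float:
        p = channel_position(ch, coords)
        return min(float(np.linalg.norm(p - a)) for a in anchors)

    best = sorted(region, key=lambda ch: (-min_dist(ch), MONTAGE18.index(ch)))
    return best[0]


def select_channels(
    psd: PSDTable,
    corr: CorrTable | None = None,
    regions: RegionMap | None = None,
    rel_margin: float = 0.10,
    coords: dict[str, tuple[float, float]] | None = None,
) -> list[str]:
    """Reduce the 18-channel montage to one channel per region (10 total).

    The central region contributes both of its channels unconditionally.
    Every other region contributes its PSD-dominant channel
    (:func:`region_winner`); regions without a dominant channel are
    resolved afterwards, in montage order, by :func:`farthest_channel`
    anchored on everything selected so far.  The result is ordered by
    montage order and always has ``len(regions) + 1`` channels (10 for
    the default map).
    """
    regions = regions or default_region_map()
    selected: list[str] = list(regions.regions[regions.central])
    uncertain: list[tuple[str, str]] = []
    for name, pair in regions.items():
        if name == regions.central:
            continue
        win = region_winner(pair, psd, rel_margin)
        if win is None:
            uncertain.append(pair)
        else:
            selected.append(win)
    uncertain.sort(key=lambda pair: min(MONTAGE18.index(c) for c in pair))
    for pair in uncertain:
        selected.append(farthest_channel(pair, selected, coords))
    return sorted(selected, key=MONTAGE18.index)


# ---------------------------------------------------------------------------
# published CHB-MIT summary tables (six records from patients 01, 03, 05)

_CHB_RECORDS = ("0103", "0104", "0301", "0302", "0513", "0516")

# per-record mean PSD, nonepilepsy then epilepsy condition, record order
# as in _CHB_RECORDS
_CHB_PSD = {
    "FP1F7": ((468, 247, 581, 256, 829, 1149),
              (1678, 1560, 3748, 3850, 4423, 5616)),
    "F7T7": ((321, 181, 367, 271, 1444, 2021),
             (1039, 834, 3337, 3725, 6948, 7081)),
    "T7P7": ((498, 184, 121, 120, 734, 1024),
             (1013, 713, 908, 2000, 4380, 3913)),
    "P7O1": ((342, 168, 79, 100, 1211, 1665),
             (651, 515, 537, 622, 4481, 5078)),
    "FP1F3": ((638, 408, 514, 405, 836, 1259),
              (2312, 1887, 4153, 4160, 5312, 5809)),
    "F3C3": ((682, 409, 112, 246, 1283, 1602),
             (1772, 1189, 1243, 1259, 9001, 8162)),
    "C3P3": ((352, 183, 83, 77, 511, 793),
             (915, 606, 604, 632, 3298, 5298)),
    "P3O1": ((544, 268, 74, 70, 835, 1362),
             (1220, 912, 379, 379, 4357, 6954)),
    "FP2F4": ((615, 419, 378, 438, 617, 686),
              (2016, 1902, 3048, 3012, 6588, 5025)),
    "F4C4": ((635, 385, 77, 200, 556, 458),
             (2092, 1623, 568, 512, 6168, 5235)),
    "C4P4": ((367, 237, 84, 104, 404, 448),
             (1288, 991, 521, 464, 4291, 2973)),
    "P4O2": ((719, 522, 75, 113, 472, 581),
             (1797, 1712, 300, 364, 4896, 3820)),
    "FP2F8": ((478, 300, 388, 371, 440, 660),
              (1710, 1456, 3067, 4035, 4482, 5577)),
    "F8T8": ((419, 300, 179, 184, 485, 627),
             (1556, 1474, 1450, 1949, 5521, 4924)),
    "T8P8": ((599, 300, 72, 118, 443, 564),
             (1995, 1277, 709, 1489, 5500, 4295)),
    "P8O2": ((691, 517, 66, 73, 409, 519),
             (2119, 2236, 279, 374, 4786, 3628)),
    "FZCZ": ((948, 508, 105, 214, 789, 737),
             (2351, 1767, 797, 693, 6453, 6070)),
    "CZPZ": ((777, 427, 70, 126, 473, 453),
             (1814, 1425, 463, 409, 4051, 2969)),
}

# channel pairs with correlation >= 0.5 in the epilepsy condition:
# (channel_a, channel_b, rho_epilepsy, rho_nonepilepsy).  The published
# summary lists C4P4-CZPZ twice; both rows are kept verbatim.
_CHB_CORR = (
    ("FP1F7", "FP1F3", 0.64, 0.58),
    ("F7T7", "F3C3", 0.77, 0.80),
    ("F7T7", "C3P3", 0.56, 0.50),
    ("T7P7", "C3P3", 0.67, 0.67),
    ("FP1F3", "FP2F4", 0.51, 0.59),
    ("F3C3", "F4C4", 0.57, 0.65),
    ("F3C3", "FZCZ", 0.70, 0.78),
    ("C3P3", "P3O1", 0.54, 0.49),
    ("C3P3", "C4P4", 0.64, 0.65),
    ("C3P3", "P4O2", 0.50, 0.50),
    ("C3P3", "CZPZ", 0.86, 0.73),
    ("P3O1", "P4O2", 0.59, 0.71),
    ("F4C4", "F8T8", 0.60, 0.74),
    ("F4C4", "FZCZ", 0.86, 0.80),
    ("C4P4", "P4O2", 0.61, 0.54),
    ("C4P4", "T8P8", 0.62, 0.60),
    ("C4P4", "CZPZ", 0.78, 0.78),
    ("C4P4", "CZPZ", 0.65, 0.52),
    ("FZCZ", "CZPZ", 0.50, 0.01),
)


def chb_psd_table() -> PSDTable:
    """The shipped six-record CHB-MIT mean-PSD summary as a PSDTable."""
    rows = []
    for ch, (nonepi, epi) in _CHB_PSD.items():
        for rec, v in zip(_CHB_RECORDS, nonepi):
            rows.append((ch, rec, "nonepilepsy", float(v)))
        for rec, v in zip(_CHB_RECORDS, epi):
            rows.append((ch, rec, "epilepsy", float(v)))
    return PSDTable(pd.DataFrame(
        rows, columns=["channel", "record", "condition", "value"]
    ))


def chb_corr_table() -> CorrTable:
    """The shipped CHB-MIT channel-correlation summary as a CorrTable."""
    rows = []
    for a, b, epi, nonepi in _CHB_CORR:
        rows.append((a, b, "epilepsy", epi))
        rows.append((a, b, "nonepilepsy", nonepi))
    return CorrTable(pd.DataFrame(
        rows, columns=["channel_a", "channel_b", "condition", "rho"]
    ))
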