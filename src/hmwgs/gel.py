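"""SDS-PAGE evidence as ordinal band-mobility ranks.

Band positions are modelled as ordinal ranks (1 = slowest / largest
apparent MW), not Rf values: the gel images support relative order only.
The default rank order shipped in ``data/mobility.tsv`` is an internally
consistent convention shared by the simulator and the caller, and can be
replaced by the user via TSV.  Bx7/Bx7OE and Dy10/Dy12 co-migrate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

from .errors import ConfigurationError, FormatError, ValidationError
from .subunits import SubunitId


@dataclass
class MobilityTable:
    """Map from subunit to ordinal mobility rank, with co-migration sets."""

    rank: dict[SubunitId, int]

    def __post_init__(self) -> None:
        if not self.rank:
            raise ValidationError("empty mobility table")

    @property
    def comigrating(self) -> list[frozenset[SubunitId]]:
        by_rank: dict[int, set[SubunitId]] = {}
        for sub, r in self.rank.items():
            by_rank.setdefault(r, set()).add(sub)
        return [frozenset(s) for s in by_rank.values() if len(s) > 1]

    def rank_of(self, sub: SubunitId) -> int:
        try:
            return self.rank[sub]
        except KeyError:
            raise ConfigurationError(f"subunit {sub} missing from mobility table") from None


@dataclass
class GelLane:
    """Observed bands of one sample, as sorted mobility ranks."""

    sample_id: str
    bands: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bands = sorted(int(b) for b in self.bands)


class GelResolution(NamedTuple):
    candidates: frozenset[SubunitId]
    no_evidence: bool


def load_mobility(path) -> MobilityTable:
    """Load a mobility TSV with columns ``type label rank``."""
    rank: dict[SubunitId, int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"type", "label", "rank"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: need columns type, label, rank")
        for i, row in enumerate(reader, start=2):
            try:
                sub = SubunitId(row["type"], row["label"])
                r = int(row["rank"])
            except (TypeError, ValueError, ValidationError) as exc:
                raise FormatError(f"{path} row {i}: {exc}") from exc
            if sub in rank:
                raise FormatError(f"{path} row {i}: duplicate subunit {sub}")
            rank[sub] = r
    return MobilityTable(rank)


def packaged_mobility() -> MobilityTable:
    with resources.as_file(resources.files("hmwgs.data") / "mobility.tsv") as p:
        return load_mobility(p)


def load_gel_lanes(path) -> dict[str, GelLane]:
    """Load lanes from a TSV with columns ``sample_id band_rank`` (one row per band)."""
    bands: dict[str, list[int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"sample_id", "band_rank"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: need columns sample_id, band_rank")
        for i, row in enumerate(reader, start=2):
            try:
                bands.setdefault(row["sample_id"], []).append(int(row["band_rank"]))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path} row {i}: {exc}") from exc
    return {sid: GelLane(sid, b) for sid, b in bands.items()}


def write_gel_lane(lane: GelLane, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tband_rank\n")
        for b in lane.bands:
            fh.write(f"{lane.sample_id}\t{b}\n")


def resolve_with_gel(
    candidates: Iterable[SubunitId], lane: GelLane, mobility: MobilityTable
) -> GelResolution:
    """Keep candidates whose mobility rank appears among the lane's bands.

    If no candidate rank is present in the lane the input is returned
    unchanged with ``no_evidence=True`` rather than an empty set.
    """
    cands = frozenset(candidates)
    if len({s.locus_type for s in cands}) > 1:
        raise ValidationError("gel resolution candidates must share a locus type")
    present = frozenset(s for s in cands if mobility.rank_of(s) in lane.bands)
    if not present:
        return GelResolution(cands, True)
    return GelResolution(present, False)
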