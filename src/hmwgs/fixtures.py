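"""Cultivar profile fixtures: 16 standards, 38 Korean cultivars, and the
prior assignments of the 32 Korean cultivars that had been analyzed
before (including the three later-corrected ones: Jonong By8,
Sinmichal By8, Sinmichal1 Dx2.2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .caller import ABSENT, CultivarProfile, PairingTable, packaged_pairing
from .errors import FormatError, ValidationError
from .subunits import SubunitId

_PROFILE_COLUMNS = ("name", "ax", "bx", "by", "dx", "dy")


@dataclass
class FixtureSet:
    standards: list[CultivarProfile]
    korean: list[CultivarProfile]
    priors: dict[str, CultivarProfile]  # keyed by cultivar name

    def __post_init__(self) -> None:
        if len(self.standards) != 16:
            raise ValidationError(f"expected 16 standards, got {len(self.standards)}")
        if len(self.korean) != 38:
            raise ValidationError(f"expected 38 Korean cultivars, got {len(self.korean)}")
        if len(self.priors) != 32:
            raise ValidationError(f"expected 32 prior profiles, got {len(self.priors)}")

    def all_profiles(self) -> list[CultivarProfile]:
        return list(self.standards) + list(self.korean)

    def by_name(self, name: str) -> CultivarProfile:
        for p in self.all_profiles():
            if p.name == name:
                return p
        raise KeyError(f"no fixture cultivar named {name!r}")


def _parse_sub(locus_type: str, label: str) -> Optional[SubunitId]:
    if label in (ABSENT, "N", ""):
        return None
    return SubunitId(locus_type, label)


def load_profiles(path, pairing: Optional[PairingTable] = None) -> list[CultivarProfile]:
    """Load profiles from a TSV with columns ``name ax bx by dx dy``.

    ``N``/``-`` mark null or absent subunits.  Profiles are validated
    against the pairing table and the Dx/Dy linkage rule.
    """
    pairing = pairing or packaged_pairing()
    profiles: list[CultivarProfile] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_PROFILE_COLUMNS) <= set(reader.fieldnames):
            raise FormatError(f"{path}: need columns {_PROFILE_COLUMNS}")
        for i, row in enumerate(reader, start=2):
            name = row["name"]
            if name in seen:
                raise FormatError(f"{path} row {i}: duplicate cultivar {name!r}")
            seen.add(name)
            try:
                dx = _parse_sub("Dx", row["dx"])
                dy = _parse_sub("Dy", row["dy"])
                if dx is None or dy is None:
                    raise ValidationError("Glu-D1 must be complete")
                profile = CultivarProfile(
                    name=name,
                    ax=_parse_sub("Ax", row["ax"]),
                    bx=_parse_sub("Bx", row["bx"]),
                    by=_parse_sub("By", row["by"]),
                    dx=dx,
                    dy=dy,
                )
                profile.validate(pairing)
            except ValidationError as exc:
                raise FormatError(f"{path} row {i}: {exc}") from exc
            profiles.append(profile)
    if not profiles:
        raise FormatError(f"{path}: no profiles")
    return profiles


def _packaged(name: str, pairing: PairingTable) -> list[CultivarProfile]:
    with resources.as_file(resources.files("hmwgs.data") / name) as p:
        return load_profiles(p, pairing)


def new_korean_names() -> frozenset[str]:
    """Korean cultivars first characterized in this workflow (no priors)."""
    names = set()
    with resources.as_file(resources.files("hmwgs.data") / "korean.tsv") as p:
        with open(p, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                if row.get("is_new") == "1":
                    names.add(row["name"])
    return frozenset(names)


def load_fixtures() -> FixtureSet:
    """The packaged fixture set (validated counts: 16 / 38 / 32)."""
    pairing = packaged_pairing()
    standards = _packaged("standards.tsv", pairing)
    korean = _packaged("korean.tsv", pairing)
    priors = {p.name: p for p in _packaged("priors.tsv", pairing)}
    return FixtureSet(standards=standards, korean=korean, priors=priors)
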