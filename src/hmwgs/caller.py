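"""Combined RT + gel + intensity + linkage identification of HMW-GS.

Pipeline: detect peaks in the HMW window, exhaustively assign peaks to
locus types (Ax/Bx/By/Dx/Dy) under composition constraints, then reduce
per-locus candidate sets with evidence in a fixed order:

1. pairing   — Bx candidates are restricted to x-type alleles that can
               pair with some By candidate (or occur alone).  By
               candidates are deliberately NOT restricted from Bx: the
               pairing table is empirical and the y-type call is the one
               that historically needed gel confirmation.
2. gel       — candidates whose mobility rank is absent from the lane
               are dropped (co-migrating subunits survive together).
3. intensity — a Bx peak still ambiguous between 7 and 7OE is called
               7OE when its area is >= threshold times the median area
               of the other HMW peaks (the overexpressed variant gives
               roughly double abundance).
4. linkage   — the y-type subunit at Glu-D1 is inferred from the x-type
               (Dx5 pairs with Dy10; Dx2/2.2/4 pair with Dy12).

A locus still holding several candidates afterwards is flagged and the
lowest-|z| candidate reported provisionally; Glu-A1 with no matching
peak is called null.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .chromatogram import Chromatogram, Peak, detect_peaks
from .config import CallConfig
from .errors import FormatError, UnassignableError, ValidationError
from .gel import GelLane, MobilityTable, resolve_with_gel
from .reference import ReferenceEntry, ReferenceTable, rt_window
from .subunits import LOCUS_TYPES, SubunitId

logger = logging.getLogger(__name__)

ABSENT = "-"  # TSV marker for an absent subunit (also "N" for Ax null)


# ---------------------------------------------------------------------------
# profiles and pairing


@dataclass(frozen=True)
class PairingTable:
    """Allowed (Bx label, By label or None) combinations at Glu-B1."""

    allowed: frozenset[tuple[str, Optional[str]]]

    def x_partners(self, by_label: Optional[str]) -> set[str]:
        return {x for x, y in self.allowed if y == by_label}

    def compatible(self, bx_label: Optional[str], by_label: Optional[str]) -> bool:
        if bx_label is None:
            return by_label is None
        return (bx_label, by_label) in self.allowed

    def feasible(self, bx_labels: set[str], by_labels: Optional[set[str]]) -> bool:
        """Can any candidate combination satisfy the table?

        ``by_labels=None`` means no By peak was assigned.
        """
        if by_labels is None:
            return any((x, None) in self.allowed for x in bx_labels)
        return any((x, y) in self.allowed for x in bx_labels for y in by_labels)


def load_pairing(path) -> PairingTable:
    """Load a pairing TSV with columns ``bx by`` ('-' meaning By absent)."""
    allowed: set[tuple[str, Optional[str]]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"bx", "by"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: need columns bx, by")
        for i, row in enumerate(reader, start=2):
            bx, by = row["bx"], row["by"]
            if not bx:
                raise FormatError(f"{path} row {i}: empty bx label")
            allowed.add((bx, None if by in (ABSENT, "", None) else by))
    if not allowed:
        raise FormatError(f"{path}: no pairs")
    return PairingTable(frozenset(allowed))


def packaged_pairing() -> PairingTable:
    with resources.as_file(resources.files("hmwgs.data") / "pairing.tsv") as p:
        return load_pairing(p)


@dataclass(frozen=True)
class CultivarProfile:
    """Alleles at the three Glu-1 loci. ``ax``/``by`` may be absent."""

    name: str
    ax: Optional[SubunitId]
    bx: Optional[SubunitId]
    by: Optional[SubunitId]
    dx: SubunitId
    dy: SubunitId

    def subunits(self) -> list[SubunitId]:
        """Expressed subunits only."""
        return [s for s in (self.ax, self.bx, self.by, self.dx, self.dy) if s is not None]

    def label_at(self, locus_type: str) -> Optional[str]:
        sub = {"Ax": self.ax, "Bx": self.bx, "By": self.by, "Dx": self.dx, "Dy": self.dy}[
            locus_type
        ]
        return None if sub is None else sub.label

    def composition(self) -> dict[str, Optional[str]]:
        return {t: self.label_at(t) for t in LOCUS_TYPES}

    def validate(self, pairing: PairingTable) -> None:
        for sub, expect in ((self.ax, "Ax"), (self.bx, "Bx"), (self.by, "By"),
                            (self.dx, "Dx"), (self.dy, "Dy")):
            if sub is not None and sub.locus_type != expect:
                raise ValidationError(f"{self.name}: {sub} is not a {expect} subunit")
        if self.dy.label == "10" and self.dx.label != "5":
            raise ValidationError(f"{self.name}: Dy10 must pair with Dx5")
        if self.dy.label == "12" and self.dx.label not in ("2", "2.2", "4"):
            raise ValidationError(f"{self.name}: Dy12 must pair with Dx2/2.2/4")
        if self.by is not None and self.bx is None:
            raise ValidationError(f"{self.name}: By present without Bx")
        if self.bx is not None and not pairing.compatible(self.bx.label,
                                                          None if self.by is None else self.by.label):
            raise ValidationError(
                f"{self.name}: Glu-B1 pair ({self.bx.label}, "
                f"{None if self.by is None else self.by.label}) not in pairing table"
            )


def infer_dy(dx: SubunitId) -> SubunitId:
    """y-type at Glu-D1 from the x-type: 5 -> 10; 2/2.2/4 -> 12."""
    if dx.locus_type != "Dx":
        raise ValidationError(f"linkage inference needs a Dx subunit, got {dx}")
    if dx.label == "5":
        return SubunitId("Dy", "10")
    if dx.label in ("2", "2.2", "4"):
        return SubunitId("Dy", "12")
    raise ValidationError(f"unknown Dx allele {dx.label!r}")


# ---------------------------------------------------------------------------
# RT matching and assignment


def match_peak(peak: Peak, table: ReferenceTable, k: float = 3.0) -> frozenset[SubunitId]:
    """All subunits whose ``mean ± k·sd`` window contains the apex."""
    out = set()
    for entry in table:
        lo, hi = rt_window(entry, k)
        if lo <= peak.apex_rt <= hi:
            out.add(entry.subunit)
    return frozenset(out)


@dataclass(frozen=True)
class PeakAssignment:
    peak: Peak
    locus_type: str
    candidates: frozenset[SubunitId]  # same-type candidates in window
    z: float  # z-score of the best candidate


def _best_z(peak: Peak, entries: Iterable[ReferenceEntry]) -> float:
    return min(abs(peak.apex_rt - e.mean_rt) / e.sd_rt if e.sd_rt > 0 else
               (0.0 if peak.apex_rt == e.mean_rt else float("inf"))
               for e in entries)


def assign_peaks(
    peaks: list[Peak],
    table: ReferenceTable,
    pairing: PairingTable,
    k: float = 3.0,
) -> list[PeakAssignment]:
    """Exhaustive injective assignment of peaks to locus types.

    Constraints: every peak keeps a non-empty same-type candidate set, at
    most one peak per locus type, Dx and Dy are both present, and the
    Glu-B1 candidates admit at least one allowed (Bx, By) combination.
    Among consistent assignments the one minimizing the summed squared
    z-scores of the best per-peak candidates wins; ties are broken by
    enumeration order over peaks sorted by apex RT (earlier apexes get
    earlier locus types first).
    """
    if len(peaks) > 8:
        raise UnassignableError(f"too many peaks ({len(peaks)}) for assignment", peaks)
    peaks = sorted(peaks, key=lambda p: p.apex_rt)
    all_cands = [match_peak(p, table, k) for p in peaks]
    if any(not c for c in all_cands):
        bad = [p for p, c in zip(peaks, all_cands) if not c]
        raise UnassignableError(
            f"{len(bad)} peak(s) match no reference window: "
            + ", ".join(f"{p.apex_rt:.3f}" for p in bad),
            bad,
        )
    per_type = [
        {t: frozenset(s for s in c if s.locus_type == t) for t in LOCUS_TYPES}
        for c in all_cands
    ]
    n = len(peaks)
    if n > len(LOCUS_TYPES):
        raise UnassignableError(f"{n} matched peaks exceed the {len(LOCUS_TYPES)} locus types", peaks)

    best: tuple[float, tuple[str, ...]] | None = None
    for types in itertools.permutations(LOCUS_TYPES, n):
        cand_sets = [per_type[i][t] for i, t in enumerate(types)]
        if any(not c for c in cand_sets):
            continue
        if "Dx" not in types or "Dy" not in types:
            continue
        bx_idx = types.index("Bx") if "Bx" in types else None
        by_idx = types.index("By") if "By" in types else None
        if by_idx is not None and bx_idx is None:
            continue
        if bx_idx is not None:
            bx_labels = {s.label for s in cand_sets[bx_idx]}
            by_labels = {s.label for s in cand_sets[by_idx]} if by_idx is not None else None
            if not pairing.feasible(bx_labels, by_labels):
                continue
        cost = 0.0
        for i, t in enumerate(types):
            z = _best_z(peaks[i], (table.entry(s) for s in cand_sets[i]))
            cost += z * z
        if best is None or cost < best[0]:
            best = (cost, types)
    if best is None:
        raise UnassignableError(
            "no consistent peak-to-locus assignment for apexes "
            + ", ".join(f"{p.apex_rt:.3f}" for p in peaks),
            peaks,
        )
    _, types = best
    out = []
    for i, t in enumerate(types):
        cands = per_type[i][t]
        out.append(
            PeakAssignment(
                peak=peaks[i],
                locus_type=t,
                candidates=cands,
                z=_best_z(peaks[i], (table.entry(s) for s in cands)),
            )
        )
    return out


def call_overexpression(
    bx_peak: Peak, other_peaks: list[Peak], threshold: float = 1.5
) -> str:
    """Return ``"7OE"`` iff area(bx) / median(other areas) >= threshold (inclusive)."""
    if not other_peaks:
        raise ValidationError("overexpression call needs at least one other peak")
    areas = sorted(p.area for p in other_peaks)
    m = len(areas)
    median = areas[m // 2] if m % 2 else 0.5 * (areas[m // 2 - 1] + areas[m // 2])
    return "7OE" if bx_peak.area / median >= threshold else "7"


# ---------------------------------------------------------------------------
# the composition call


@dataclass
class LocusCall:
    """Working state for one assigned locus type during evidence reduction."""

    assignment: PeakAssignment
    candidates: frozenset[SubunitId]
    evidence: str  # resolving evidence kind once the set is a singleton


@dataclass
class CallResult:
    profile: CultivarProfile
    per_peak: list[dict]  # apex_rt, height, area, locus_type, call, candidates, z
    evidence: dict[str, str]  # locus type -> rt|gel|intensity|linkage|pairing|absent
    flags: list[str]

    def exact_match(self, truth: CultivarProfile) -> bool:
        return self.profile.composition() == truth.composition()

    def to_dict(self) -> dict:
        return {
            "sample_id": self.profile.name,
            "composition": self.profile.composition(),
            "per_peak": self.per_peak,
            "evidence": self.evidence,
            "flags": list(self.flags),
        }


def _z_of(peak: Peak, entry: ReferenceEntry) -> float:
    if entry.sd_rt == 0:
        return 0.0 if peak.apex_rt == entry.mean_rt else float("inf")
    return (peak.apex_rt - entry.mean_rt) / entry.sd_rt


def call_composition(
    trace: Chromatogram,
    table: ReferenceTable,
    pairing: PairingTable,
    mobility: MobilityTable,
    lane: Optional[GelLane] = None,
    config: Optional[CallConfig] = None,
) -> CallResult:
    """Run the full identification pipeline on one trace."""
    cfg = config or CallConfig()
    peaks = detect_peaks(
        trace, window=cfg.window, min_height=cfg.min_height, smooth_width=cfg.smooth_width
    )
    flags: list[str] = []
    matched: list[Peak] = []
    for p in peaks:
        if match_peak(p, table, cfg.k):
            matched.append(p)
        else:
            flags.append(f"no-match: peak at {p.apex_rt:.3f} min matches no reference window")

    assignments = assign_peaks(matched, table, pairing, cfg.k)
    loci: dict[str, LocusCall] = {
        a.locus_type: LocusCall(a, a.candidates, "rt") for a in assignments
    }

    # 1) pairing: restrict Bx by the By candidates (or By absence)
    if "Bx" in loci:
        by_labels = {s.label for s in loci["By"].candidates} if "By" in loci else None
        allowed_x: set[str] = set()
        for y in (by_labels if by_labels is not None else {None}):
            allowed_x |= pairing.x_partners(y)
        bx = loci["Bx"]
        reduced = frozenset(s for s in bx.candidates if s.label in allowed_x)
        if reduced and reduced < bx.candidates:
            bx.candidates = reduced
            bx.evidence = "pairing"

    # 2) gel
    if lane is not None:
        for lc in loci.values():
            if len(lc.candidates) > 1:
                res = resolve_with_gel(lc.candidates, lane, mobility)
                if res.no_evidence:
                    flags.append(
                        f"no-gel-evidence: lane lacks bands for {lc.assignment.locus_type} "
                        f"candidates"
                    )
                elif res.candidates < lc.candidates:
                    lc.candidates = res.candidates
                    if len(lc.candidates) == 1:
                        lc.evidence = "gel"

    # 3) intensity: Bx7 vs Bx7OE by relative peak area
    if "Bx" in loci:
        bx = loci["Bx"]
        if {s.label for s in bx.candidates} == {"7", "7OE"}:
            others = [a.peak for a in assignments if a.locus_type != "Bx"]
            label = call_overexpression(bx.assignment.peak, others, cfg.oe_threshold)
            bx.candidates = frozenset(s for s in bx.candidates if s.label == label)
            bx.evidence = "intensity"

    # 4) linkage: Dy from Dx
    if "Dy" in loci and "Dx" in loci:
        dy = loci["Dy"]
        inferred = {infer_dy(dx) for dx in loci["Dx"].candidates}
        if len(inferred) == 1:
            target = next(iter(inferred))
            if target in dy.candidates:
                if len(dy.candidates) > 1:
                    dy.candidates = frozenset({target})
                    dy.evidence = "linkage"
            else:
                flags.append(
                    f"linkage-conflict: Dx implies {target} but Dy candidates are "
                    f"{sorted(str(s) for s in dy.candidates)}"
                )

    # finalize: provisional lowest-|z| choice for any remaining ambiguity
    final: dict[str, Optional[SubunitId]] = {t: None for t in LOCUS_TYPES}
    evidence: dict[str, str] = {}
    per_peak: list[dict] = []
    for t, lc in loci.items():
        if len(lc.candidates) == 1:
            chosen = next(iter(lc.candidates))
            evidence[t] = lc.evidence
        else:
            chosen = min(lc.candidates, key=lambda s: abs(_z_of(lc.assignment.peak, table.entry(s))))
            evidence[t] = "rt"
            flags.append(
                f"ambiguous-{t}: {sorted(str(s) for s in lc.candidates)}; "
                f"provisional {chosen}"
            )
        final[t] = chosen
        p = lc.assignment.peak
        per_peak.append(
            {
                "apex_rt": round(p.apex_rt, 3),
                "height": round(p.height, 3),
                "area": round(p.area, 3),
                "locus_type": t,
                "call": str(chosen),
                "candidates": sorted(str(s) for s in lc.candidates),
                "z": round(_z_of(p, table.entry(chosen)), 3),
            }
        )
    for t in LOCUS_TYPES:
        if t not in loci:
            evidence[t] = "absent"

    if final["Dx"] is None or final["Dy"] is None:
        raise UnassignableError("Glu-D1 subunits missing from assignment", peaks)
    profile = CultivarProfile(
        name=trace.sample_id,
        ax=final["Ax"],
        bx=final["Bx"],
        by=final["By"],
        dx=final["Dx"],
        dy=final["Dy"],
    )
    per_peak.sort(key=lambda d: d["apex_rt"])
    result = CallResult(profile=profile, per_peak=per_peak, evidence=evidence, flags=flags)
    logger.info(
        "call %s: composition=%s evidence=%s flags=%d",
        trace.sample_id, profile.composition(), evidence, len(flags),
    )
    return result


def compare_to_prior(
    result: CallResult, prior: CultivarProfile
) -> list[tuple[str, Optional[str], Optional[str]]]:
    """Differences between a call and a prior profile, per locus-type slot."""
    if result.profile.name != prior.name:
        raise ValidationError(
            f"cultivar name mismatch: called {result.profile.name!r} vs prior {prior.name!r}"
        )
    out = []
    for t in LOCUS_TYPES:
        new, old = result.profile.label_at(t), prior.label_at(t)
        if new != old:
            out.append((t, old, new))
    return out
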