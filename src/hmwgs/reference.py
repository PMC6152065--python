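"""Retention-time reference statistics and the resolvability structure.

The packaged reference table stores, for each of the 20 canonical
subunits, the mean retention time (RT, minutes) and its standard
deviation over replicate runs of standard cultivars, together with
replication counts and the relative standard deviation (RSD, percent).

Classification windows are ``mean ± k·sd`` with a default ``k`` of 3.
Groups of same-type subunits whose windows mutually contain each other's
means cannot be told apart by RT alone; those are the ambiguity groups,
each annotated with the kind of extra evidence that resolves it
(gel mobility, peak intensity, or x/y linkage).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, InsufficientDataError, ValidationError
from .subunits import LOCUS_TYPES, SubunitId

#: printed-rounding slack for the RSD consistency check, in percent
RSD_TOLERANCE = 0.005

DEFAULT_HMW_WINDOW = (25.0, 42.0)
DEFAULT_K = 3.0

_REFERENCE_COLUMNS = ("type", "label", "mean_rt", "sd_rt", "n_cultivars", "n_analyses", "rsd_pct")


@dataclass(frozen=True)
class ReferenceEntry:
    """Per-subunit RT statistics from replicate reference runs."""

    subunit: SubunitId
    mean_rt: float
    sd_rt: float
    n_cultivars: int
    n_analyses: int
    rsd_pct: float

    def __post_init__(self) -> None:
        if not self.mean_rt > 0:
            raise ValidationError(f"{self.subunit}: mean_rt must be positive")
        if self.sd_rt < 0:
            raise ValidationError(f"{self.subunit}: sd_rt must be non-negative")
        if not (self.n_analyses >= self.n_cultivars >= 1):
            raise ValidationError(f"{self.subunit}: need n_analyses >= n_cultivars >= 1")
        implied = 100.0 * self.sd_rt / self.mean_rt
        if abs(self.rsd_pct - implied) > RSD_TOLERANCE:
            raise ValidationError(
                f"{self.subunit}: rsd_pct {self.rsd_pct} inconsistent with "
                f"100*sd/mean = {implied:.4f}"
            )


@dataclass(frozen=True)
class AmbiguityGroup:
    """Same-type subunits indistinguishable by RT, plus how to resolve them."""

    members: frozenset[SubunitId]
    resolution: str  # one of {"gel", "intensity", "linkage"}

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("ambiguity group needs >= 2 members")
        if len({s.locus_type for s in self.members}) != 1:
            raise ValidationError("ambiguity group members must share a locus type")
        if self.resolution not in ("gel", "intensity", "linkage"):
            raise ValidationError(f"unknown resolution {self.resolution!r}")

    @property
    def locus_type(self) -> str:
        return next(iter(self.members)).locus_type


@dataclass
class ReferenceTable:
    """A validated collection of :class:`ReferenceEntry`, one per subunit."""

    entries: dict[SubunitId, ReferenceEntry] = field(default_factory=dict)
    hmw_window: tuple[float, float] = DEFAULT_HMW_WINDOW

    def __post_init__(self) -> None:
        lo, hi = self.hmw_window
        for entry in self.entries.values():
            if not (lo <= entry.mean_rt <= hi):
                raise ValidationError(
                    f"{entry.subunit}: mean RT {entry.mean_rt} outside HMW window {self.hmw_window}"
                )

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, sub: SubunitId) -> ReferenceEntry:
        try:
            return self.entries[sub]
        except KeyError:
            raise KeyError(f"subunit {sub} not in reference table") from None

    def by_type(self, locus_type: str) -> list[ReferenceEntry]:
        return [e for e in self.entries.values() if e.subunit.locus_type == locus_type]


@dataclass(frozen=True)
class RtStats:
    """Summary of replicate RTs: location, spread, quartiles, whiskers, CI."""

    mean: float
    sd: float
    rsd_pct: float
    n: int
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    ci_lo: float
    ci_hi: float

    def __post_init__(self) -> None:
        if not (self.whisker_lo <= self.q1 <= self.median <= self.q3 <= self.whisker_hi):
            raise ValidationError("whisker/quartile ordering violated")
        if not (self.ci_lo <= self.mean <= self.ci_hi):
            raise ValidationError("confidence interval must contain the mean")


def load_reference(path, hmw_window: tuple[float, float] = DEFAULT_HMW_WINDOW) -> ReferenceTable:
    """Load a reference TSV with columns ``type label mean_rt sd_rt n_cultivars n_analyses rsd_pct``.

    Raises :class:`FormatError` naming the offending row for missing
    columns, duplicate subunits or non-numeric fields.
    """
    entries: dict[SubunitId, ReferenceEntry] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty reference file")
        missing = [c for c in _REFERENCE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        n_rows = 0
        for i, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                sub = SubunitId(row["type"], row["label"])
                entry = ReferenceEntry(
                    subunit=sub,
                    mean_rt=float(row["mean_rt"]),
                    sd_rt=float(row["sd_rt"]),
                    n_cultivars=int(row["n_cultivars"]),
                    n_analyses=int(row["n_analyses"]),
                    rsd_pct=float(row["rsd_pct"]),
                )
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path} row {i}: bad field ({exc})") from exc
            except ValidationError as exc:
                raise FormatError(f"{path} row {i}: {exc}") from exc
            if sub in entries:
                raise FormatError(f"{path} row {i}: duplicate subunit {sub}")
            entries[sub] = entry
        if n_rows == 0:
            raise FormatError(f"{path}: no data rows")
    return ReferenceTable(entries=entries, hmw_window=hmw_window)


def packaged_reference() -> ReferenceTable:
    """The reference table shipped with the package (20 canonical subunits)."""
    with resources.as_file(resources.files("hmwgs.data") / "reference_rt.tsv") as p:
        return load_reference(p)


def summarize_rts(replicates: Sequence[float]) -> RtStats:
    """Summarize replicate RTs.

    Sample SD uses the n-1 denominator; quartiles use linear
    interpolation; whiskers are the most extreme observations within
    1.5*IQR of the quartiles; the CI is the 95% normal approximation
    ``mean ± 1.96·sd/sqrt(n)``.
    """
    x = np.asarray(list(replicates), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 replicates, got {x.size}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else math.inf
    q1, med, q3 = (float(v) for v in np.percentile(x, [25, 50, 75], method="linear"))
    iqr = q3 - q1
    lo_cut, hi_cut = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    # whiskers extend outward from the box, so clamp at the quartiles
    # (interpolated quartiles can exceed every retained point on discrete data)
    whisker_lo = min(q1, float(x[x >= lo_cut].min()))
    whisker_hi = max(q3, float(x[x <= hi_cut].max()))
    half = 1.96 * sd / math.sqrt(x.size)
    return RtStats(
        mean=mean, sd=sd, rsd_pct=rsd, n=int(x.size),
        q1=q1, median=med, q3=q3,
        whisker_lo=whisker_lo, whisker_hi=whisker_hi,
        ci_lo=mean - half, ci_hi=mean + half,
    )


def rt_window(entry: ReferenceEntry, k: float = DEFAULT_K) -> tuple[float, float]:
    """Classification window ``[mean − k·sd, mean + k·sd]``."""
    if not k > 0:
        raise ValidationError("window multiplier k must be positive")
    return (entry.mean_rt - k * entry.sd_rt, entry.mean_rt + k * entry.sd_rt)


def _mean_in_window(a: ReferenceEntry, b: ReferenceEntry, k: float) -> bool:
    lo, hi = rt_window(b, k)
    return lo <= a.mean_rt <= hi


def derive_ambiguity_groups(table: ReferenceTable, k: float = DEFAULT_K) -> list[AmbiguityGroup]:
    """Connected components of mutual mean-in-window containment, per locus type.

    Two same-type entries are linked when either mean lies inside the
    other's k-window.  Components of size >= 2 are returned with a
    placeholder ``gel`` resolution (the resolution kind is evidence
    metadata, not derivable from RT statistics alone); singletons are
    RT-resolvable and dropped.
    """
    groups: list[AmbiguityGroup] = []
    for locus_type in LOCUS_TYPES:
        entries = sorted(table.by_type(locus_type), key=lambda e: e.mean_rt)
        n = len(entries)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = entries[i], entries[j]
                if _mean_in_window(a, b, k) or _mean_in_window(b, a, k):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        comps: dict[int, set[SubunitId]] = {}
        for i in range(n):
            comps.setdefault(find(i), set()).add(entries[i].subunit)
        for members in comps.values():
            if len(members) >= 2:
                groups.append(AmbiguityGroup(frozenset(members), "gel"))
    return groups


def canonical_ambiguity_groups() -> list[AmbiguityGroup]:
    """The five RT-ambiguity groups and their resolving evidence."""
    S = SubunitId
    return [
        AmbiguityGroup(frozenset({S("Ax", "1"), S("Ax", "2*")}), "gel"),
        AmbiguityGroup(frozenset({S("Bx", "7"), S("Bx", "7OE")}), "intensity"),
        AmbiguityGroup(
            frozenset({S("By", "8*"), S("By", "9"), S("By", "18"), S("By", "20y")}), "gel"
        ),
        AmbiguityGroup(frozenset({S("Dx", "2"), S("Dx", "4")}), "gel"),
        AmbiguityGroup(frozenset({S("Dy", "10"), S("Dy", "12")}), "linkage"),
    ]


def gel_resolution_members() -> frozenset[SubunitId]:
    """All subunits belonging to a gel-resolved ambiguity group."""
    out: set[SubunitId] = set()
    for g in canonical_ambiguity_groups():
        if g.resolution == "gel":
            out |= g.members
    return frozenset(out)
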