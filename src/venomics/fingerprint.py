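"""Intact-mass fingerprint: loading, artifact curation and summaries.

A fingerprint is the list of deconvolved neutral masses ([M]) of a whole
venom, grouped into retention-time bins.  Deconvolution reports
monoisotopic masses below 3000 Da and average masses at or above 3000 Da;
that kind label decides which theoretical scale a peak is compared on and
which pairing tolerance applies.

Raw fingerprints carry satellite peaks that are chemistry, not biology:
cation adducts (Na/K/NH4 replacing or joining a proton), methionine/
tryptophan oxidation, water loss, deamidation and neutral CO loss.  The
curation step removes the derived member of every peak pair whose mass
difference matches one of these delta rules, iterating to a fixed point.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "MASS_KIND_BOUNDARY",
    "MassPeak",
    "DeltaRule",
    "Fingerprint",
    "Removal",
    "FingerprintSummary",
    "DEFAULT_DELTA_RULES",
    "DEFAULT_TOLERANCE",
    "mass_kind_for",
    "load_fingerprint",
    "load_fingerprint_tsv",
    "write_fingerprint_tsv",
    "reference_fingerprint",
    "artifact_filter",
    "summarize_fingerprint",
    "mass_histogram",
]

log = logging.getLogger(__name__)

#: below this mass the deconvolved value is monoisotopic; at or above it,
#: average.  The boundary itself is average-kind.
MASS_KIND_BOUNDARY = 3000.0


def mass_kind_for(mass: float) -> str:
    """Pure function of mass: 'mono' strictly below 3000 Da, else 'average'."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    return "mono" if mass < MASS_KIND_BOUNDARY else "average"


@dataclass(frozen=True)
class MassPeak:
    mass: float
    rt_bin: tuple[float, float]
    mass_kind: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not self.rt_bin[0] < self.rt_bin[1]:
            raise ValueError(f"rt_bin start must precede end: {self.rt_bin}")
        expected = mass_kind_for(self.mass)
        if not self.mass_kind:
            object.__setattr__(self, "mass_kind", expected)
        elif self.mass_kind != expected:
            raise ValueError(
                f"mass_kind {self.mass_kind!r} inconsistent with the 3000 Da "
                f"rule for mass {self.mass}"
            )


@dataclass(frozen=True)
class DeltaRule:
    """A mass offset identifying a derived (artifact) peak.

    ``derived_is`` states which member of a matching pair is the artifact:
    adducts, oxidations and deamidations add mass (heavier is derived);
    dehydration and CO loss remove mass (lighter is derived).
    """

    name: str
    delta: float
    derived_is: str  # "heavier" | "lighter"

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError("delta must be non-zero")
        if self.derived_is not in ("heavier", "lighter"):
            raise ValueError("derived_is must be 'heavier' or 'lighter'")


#: Delta values from the Fiehn-lab adduct calculator conventions plus the
#: standard modification masses; user-extensible because the categories,
#: not the values, are fixed.
DEFAULT_DELTA_RULES: tuple[DeltaRule, ...] = (
    DeltaRule("sodium adduct", +21.98194, "heavier"),
    DeltaRule("potassium adduct", +37.95588, "heavier"),
    DeltaRule("ammonium adduct", +17.02655, "heavier"),
    DeltaRule("oxidation", +15.99491, "heavier"),
    DeltaRule("deamidation", +0.98402, "heavier"),
    DeltaRule("dehydration", -18.01056, "lighter"),
    DeltaRule("CO loss", -27.99491, "lighter"),
)

#: pairing tolerance in Da per mass kind; a pair uses the mono tolerance
#: only when both members are mono-kind (deconvolution precision differs)
DEFAULT_TOLERANCE: dict[str, float] = {"mono": 0.02, "average": 0.5}

_MAX_FILTER_PASSES = 10


@dataclass(frozen=True)
class Fingerprint:
    peaks: tuple[MassPeak, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(p.mass for p in self.peaks)


def load_fingerprint(
    rows: Iterable[tuple[tuple[float, float], Sequence[float]]],
    provenance: str = "",
) -> Fingerprint:
    """Build a fingerprint from (rt_bin, mass list) rows.

    Bins may repeat (rows are merged) but distinct bins must not overlap.
    Malformed masses are rejected with their row/column position.
    """
    peaks: list[MassPeak] = []
    bins: list[tuple[float, float]] = []
    for i, (rt_bin, masses) in enumerate(rows):
        rt_bin = (float(rt_bin[0]), float(rt_bin[1]))
        if rt_bin not in bins:
            for other in bins:
                if rt_bin[0] < other[1] and other[0] < rt_bin[1]:
                    raise ValueError(
                        f"row {i}: bin {rt_bin} overlaps bin {other}"
                    )
            bins.append(rt_bin)
        for j, m in enumerate(masses):
            try:
                m = float(m)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"row {i}, mass {j}: not a number: {m!r}") from exc
            if m <= 0:
                raise ValueError(f"row {i}, mass {j}: non-positive mass {m}")
            peaks.append(MassPeak(m, rt_bin))
    return Fingerprint(tuple(peaks), provenance)


def load_fingerprint_tsv(path: Union[str, Path]) -> Fingerprint:
    """Read a long-format TSV with columns rt_start, rt_end, mass."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"rt_start", "rt_end", "mass"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    grouped: dict[tuple[float, float], list[float]] = {}
    for _, row in df.iterrows():
        grouped.setdefault(
            (float(row["rt_start"]), float(row["rt_end"])), []
        ).append(row["mass"])
    return load_fingerprint(grouped.items(), provenance=str(path))


def write_fingerprint_tsv(fingerprint: Fingerprint, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("rt_start\trt_end\tmass\tmass_kind\n")
        for p in fingerprint.peaks:
            fh.write(
                f"{p.rt_bin[0]:g}\t{p.rt_bin[1]:g}\t{p.mass}\t{p.mass_kind}\n"
            )


def reference_fingerprint() -> Fingerprint:
    """The packaged whole-venom LC-MS fingerprint (135 deconvolved masses
    in 20-minute retention-time bins)."""
    ref = resources.files("venomics.data").joinpath("tatrox_fingerprint.tsv")
    with resources.as_file(ref) as path:
        fp = load_fingerprint_tsv(path)
    return Fingerprint(fp.peaks, provenance="tatrox_fingerprint")


# ---------------------------------------------------------------------------
# artifact curation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Removal:
    kept: MassPeak
    removed: MassPeak
    rule: str


def _pair_tolerance(
    a: MassPeak, b: MassPeak, tolerance: Union[float, dict, None]
) -> float:
    if tolerance is None:
        tolerance = DEFAULT_TOLERANCE
    if isinstance(tolerance, dict):
        kind = "mono" if a.mass_kind == b.mass_kind == "mono" else "average"
        return tolerance[kind]
    return float(tolerance)


def artifact_filter(
    fingerprint: Fingerprint,
    rules: Optional[Sequence[DeltaRule]] = None,
    tolerance: Union[float, dict, None] = None,
    same_bin_only: bool = True,
) -> tuple[Fingerprint, list[Removal]]:
    """Remove adduct/modification satellites, iterating to a fixed point.

    For every surviving peak pair (restricted to co-eluting peaks when
    ``same_bin_only``) whose mass difference matches a rule delta within
    the pairing tolerance, the derived member is removed and the removal
    logged.  A peak removed within a pass may still anchor further
    removals in that pass, so satellite chains (e.g. double oxidation)
    collapse onto the genuine parent.  The curated set is always a subset
    of the input; survivors plus removals partition it.
    """
    rules = DEFAULT_DELTA_RULES if rules is None else tuple(rules)
    max_delta = max(abs(r.delta) for r in rules)
    tol_map = DEFAULT_TOLERANCE if tolerance is None else tolerance
    tol_cap = max(tol_map.values()) if isinstance(tol_map, dict) else float(tol_map)
    alive: list[MassPeak] = sorted(
        fingerprint.peaks, key=lambda p: (p.mass, p.rt_bin)
    )
    removals: list[Removal] = []
    for pass_no in range(_MAX_FILTER_PASSES):
        anchors = list(alive)
        removed_now: set[int] = set()
        for i, low in enumerate(anchors):
            for j in range(i + 1, len(anchors)):
                high = anchors[j]
                diff = high.mass - low.mass
                if diff > max_delta + tol_cap:
                    break  # sorted by mass: no rule can match further out
                if same_bin_only and low.rt_bin != high.rt_bin:
                    continue
                tol = _pair_tolerance(low, high, tol_map)
                for rule in rules:
                    if abs(diff - abs(rule.delta)) <= tol:
                        if rule.derived_is == "heavier":
                            victim, kept = j, low
                        else:
                            victim, kept = i, high
                        if victim not in removed_now:
                            removed_now.add(victim)
                            removals.append(
                                Removal(kept, anchors[victim], rule.name)
                            )
                            log.info(
                                "artifact_filter: removed %.4f (kept %.4f, %s)",
                                anchors[victim].mass, kept.mass, rule.name,
                            )
                        break
        if not removed_now:
            break
        alive = [p for k, p in enumerate(anchors) if k not in removed_now]
    else:
        log.warning(
            "artifact_filter: no fixed point after %d passes; returning "
            "the current survivor set (pathological delta chain?)",
            _MAX_FILTER_PASSES,
        )
    order = {p: k for k, p in enumerate(fingerprint.peaks)}
    survivors = tuple(sorted(alive, key=lambda p: order[p]))
    curated = Fingerprint(survivors, provenance=fingerprint.provenance)
    return curated, removals


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def _round_int(value: float) -> int:
    return int(Decimal(repr(value)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FingerprintSummary:
    count: int
    min_mass: float
    max_mass: float
    median_mass: float

    @property
    def min_rounded(self) -> int:
        return _round_int(self.min_mass)

    @property
    def max_rounded(self) -> int:
        return _round_int(self.max_mass)

    @property
    def median_rounded(self) -> int:
        return _round_int(self.median_mass)


def summarize_fingerprint(fingerprint: Fingerprint) -> FingerprintSummary:
    """Order statistics of the peak masses (median of an even count is the
    mean of the middle pair)."""
    if not fingerprint.peaks:
        raise ValueError("empty fingerprint")
    masses = fingerprint.masses
    return FingerprintSummary(
        count=len(masses),
        min_mass=min(masses),
        max_mass=max(masses),
        median_mass=float(statistics.median(masses)),
    )


def mass_histogram(
    fingerprint: Fingerprint, bin_width: float
) -> dict[tuple[float, float], tuple[int, float]]:
    """Counts and fractions per [k*w, (k+1)*w) mass bin (empty bins between
    occupied ones included, so the histogram plots without gaps)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not fingerprint.peaks:
        return {}
    counts = Counter(int(p.mass // bin_width) for p in fingerprint.peaks)
    total = len(fingerprint.peaks)
    return {
        (k * bin_width, (k + 1) * bin_width): (counts[k], counts[k] / total)
        for k in range(min(counts), max(counts) + 1)
    }
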