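"""Two-generation fertility projection.

A founder female's fitness is evaluated not by her own brood (F1) but by
the projected fertility of her grand-offspring (F2): each F1 female's
lifetime fertility depends on the clutch size she developed in, so two
founders with identical F1 offspring counts but different clutch-size
profiles differ in F2 fertility.  This module distributes a founder's
offspring across host eggs according to empirical clutch-size
frequencies, assigns sexes (the species' ratio is 3:1 male:female),
and projects and compares F2 fertility between experimental groups.

Eggs laid into "fictitious" hosts (a host species that accepts
oviposition but cannot support larval development) spend the founder's
egg budget without producing any emerging offspring, so they depress
both F1 and F2 fertility.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clutch import ClutchConfig, FertilityModel, fertility_of_clutch

__all__ = [
    "ClutchSizeDistribution",
    "HostEggRecord",
    "FounderOutcome",
    "ProjectionResult",
    "allocate_offspring",
    "assign_sexes",
    "project_f2",
    "compare_scenarios",
    "project_from_frequencies",
    "projections_table",
    "founders_to_table",
    "table_to_founders",
    "read_founders_csv",
    "write_founders_csv",
]

logger = logging.getLogger("flavipes")

HOST_SPECIES = ("native", "fictitious")
SUBSTRATES = ("usual_plant", "fictitious_plant", "control_paper")

#: column order of the tidy per-host-egg table shared across the package
TIDY_COLUMNS = [
    "founder_id",
    "group",
    "substrate",
    "host_species",
    "parasitized",
    "clutch_size",
    "n_females",
    "emerged",
]


# ---------------------------------------------------------------------------
# clutch-size distribution
# ---------------------------------------------------------------------------

class ClutchSizeDistribution:
    """Frequencies over clutch sizes 1..max, used to distribute offspring.

    Weights need not be normalized; they must be non-negative with at
    least one positive entry and integer keys >= 1.
    """

    def __init__(self, weights: dict[int, float]):
        if not weights:
            raise ValueError("clutch-size distribution needs at least one weight")
        clean: dict[int, float] = {}
        for size, w in weights.items():
            size = int(size)
            if size < 1:
                raise ValueError(f"clutch size {size} < 1 in distribution")
            if w < 0:
                raise ValueError(f"negative weight {w} for clutch size {size}")
            if w > 0:
                clean[size] = float(w)
        if not clean:
            raise ValueError("clutch-size distribution needs a positive weight")
        total = sum(clean.values())
        self.weights = {s: clean[s] / total for s in sorted(clean)}

    @property
    def sizes(self) -> list[int]:
        return list(self.weights)

    @property
    def max_size(self) -> int:
        return max(self.weights)

    @property
    def mean(self) -> float:
        return sum(s * w for s, w in self.weights.items())

    def probabilities(self) -> np.ndarray:
        return np.array([self.weights[s] for s in self.sizes])

    def truncated(self, max_size: int) -> "ClutchSizeDistribution":
        """Restrict support to sizes <= ``max_size`` and renormalize."""
        kept = {s: w for s, w in self.weights.items() if s <= max_size}
        if not kept:
            raise ValueError(
                f"truncation at {max_size} leaves no support "
                f"(smallest size is {min(self.weights)})"
            )
        return ClutchSizeDistribution(kept)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.choice(self.sizes, size=n, p=self.probabilities())

    def __eq__(self, other) -> bool:
        return isinstance(other, ClutchSizeDistribution) and self.weights == other.weights

    def __repr__(self) -> str:
        return f"ClutchSizeDistribution({self.weights})"


# ---------------------------------------------------------------------------
# experimental records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostEggRecord:
    """One offered host egg and its fate."""

    host_species: str
    substrate: str
    parasitized: bool
    clutch: ClutchConfig | None = None
    offspring_emerged: bool = False

    def __post_init__(self) -> None:
        if self.host_species not in HOST_SPECIES:
            raise ValueError(f"host_species must be one of {HOST_SPECIES}")
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"substrate must be one of {SUBSTRATES}")
        if self.parasitized != (self.clutch is not None):
            raise ValueError("clutch must be present iff the egg is parasitized")
        if self.host_species == "fictitious" and self.offspring_emerged:
            raise ValueError("offspring cannot emerge from a fictitious host")


@dataclass(frozen=True)
class FounderOutcome:
    """All host-egg records of one founder female."""

    founder_id: str
    group: str
    hosts: tuple[HostEggRecord, ...]

    def __init__(self, founder_id: str, group: str, hosts) -> None:
        object.__setattr__(self, "founder_id", str(founder_id))
        object.__setattr__(self, "group", str(group))
        object.__setattr__(self, "hosts", tuple(hosts))

    @property
    def eggs_laid(self) -> int:
        """Total eggs laid, including those wasted on fictitious hosts."""
        return sum(h.clutch.size for h in self.hosts if h.parasitized)

    @property
    def f1_fertility(self) -> int:
        """Emerged F1 offspring: clutches in parasitized native hosts."""
        return sum(
            h.clutch.size
            for h in self.hosts
            if h.parasitized and h.host_species == "native"
        )

    @property
    def f1_females(self) -> int:
        return sum(
            h.clutch.females
            for h in self.hosts
            if h.parasitized and h.host_species == "native"
        )


@dataclass(frozen=True)
class ProjectionResult:
    """Per-founder two-generation fitness summary."""

    founder_id: str
    f1_eggs_laid: int
    f1_fertility: int
    f1_females: int
    f2_fertility: float
    mean_offspring_fertility: float | None  # None when no females emerged


# ---------------------------------------------------------------------------
# offspring allocation
# ---------------------------------------------------------------------------

def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing to ``total``."""
    floors = np.floor(targets).astype(int)
    deficit = total - int(floors.sum())
    if deficit > 0:
        order = np.argsort(-(targets - floors), kind="stable")
        floors[order[:deficit]] += 1
    return floors


def _repair_sizes(
    sizes: list[int], total: int, n_hosts: int, max_clutch: int
) -> list[int]:
    """Deterministically adjust a multiset of clutch sizes to exact feasibility.

    Ensures sum == total, every size in 1..max_clutch and count <= n_hosts.
    Overshoot is shaved off the largest clutches, undershoot is added to
    the smallest clutches (or new singleton clutches while hosts remain);
    excess clutches are merged smallest-first.
    """
    sizes = sorted((s for s in sizes if s > 0), reverse=True)
    # fix the total
    while sum(sizes) > total:
        sizes[0] -= 1
        if sizes[0] == 0:
            sizes.pop(0)
        sizes.sort(reverse=True)
    while sum(sizes) < total:
        grown = False
        for i in range(len(sizes) - 1, -1, -1):  # smallest first
            if sizes[i] < max_clutch:
                sizes[i] += 1
                grown = True
                break
        if not grown:
            if len(sizes) >= n_hosts:
                raise ValueError(
                    f"cannot place {total} offspring in {n_hosts} hosts "
                    f"with max clutch {max_clutch}"
                )
            sizes.append(1)
        sizes.sort(reverse=True)
    # fix the host count by merging the two smallest clutches
    while len(sizes) > n_hosts:
        if len(sizes) < 2 or sizes[-1] + sizes[-2] > max_clutch:
            raise ValueError(
                f"cannot place {total} offspring in {n_hosts} hosts "
                f"with max clutch {max_clutch}"
            )
        merged = sizes.pop() + sizes.pop()
        sizes.append(merged)
        sizes.sort(reverse=True)
    return sizes


def allocate_offspring(
    total_offspring: int,
    n_hosts: int,
    dist: ClutchSizeDistribution,
    mode: str = "expected",
    seed: int | None = None,
    max_clutch: int = 7,
) -> list[int]:
    """Distribute ``total_offspring`` across at most ``n_hosts`` host eggs.

    Returns the clutch sizes of the parasitized hosts (possibly fewer
    than ``n_hosts``), each in 1..``max_clutch``, summing exactly to
    ``total_offspring``.

    ``mode="expected"`` is deterministic: the count of clutches of each
    size is set to its frequency-proportional expectation, rounded by
    largest remainder and repaired to exact feasibility.  ``"sampled"``
    draws clutch sizes sequentially from ``dist`` truncated to the
    remaining budget, restarting on dead ends; reproducible given
    ``seed``.
    """
    if total_offspring < 0 or n_hosts < 0:
        raise ValueError("total_offspring and n_hosts must be non-negative")
    if total_offspring == 0:
        return []
    if total_offspring > n_hosts * max_clutch:
        raise ValueError(
            f"infeasible: {total_offspring} offspring exceed "
            f"{n_hosts} hosts x max clutch {max_clutch}"
        )
    if mode == "expected":
        sizes_support = np.array(dist.sizes)
        probs = dist.probabilities()
        mean = float(np.sum(sizes_support * probs))
        # expected number of clutches of each size, scaled so offspring sum
        # to the total; number of clutches rounded to nearest
        n_clutches = max(1, int(round(total_offspring / mean)))
        n_clutches = min(n_clutches, n_hosts)
        counts = _largest_remainder(probs * n_clutches, n_clutches)
        sizes = [int(s) for s, c in zip(sizes_support, counts) for _ in range(c)]
        sizes = [min(s, max_clutch) for s in sizes]
        return _repair_sizes(sizes, total_offspring, n_hosts, max_clutch)
    if mode == "sampled":
        if seed is None:
            seed = int(np.random.SeedSequence().entropy % (2**31))
            logger.info("allocate_offspring: no seed supplied, drew seed=%d", seed)
        rng = np.random.default_rng(seed)
        capped = dist.truncated(max_clutch) if dist.max_size > max_clutch else dist
        for _attempt in range(1000):
            sizes: list[int] = []
            remaining = total_offspring
            while remaining > 0 and len(sizes) < n_hosts:
                # a draw may not strand a remainder below the support minimum
                cap = min(remaining, capped.max_size)
                try:
                    trunc = capped.truncated(cap)
                except ValueError:
                    break  # remaining < smallest size: dead end, restart
                draw = int(trunc.sample(rng, 1)[0])
                sizes.append(draw)
                remaining -= draw
            if remaining == 0:
                return sizes
        # systematic dead ends: fall back to the deterministic repair path
        logger.warning(
            "sampled allocation failed after 1000 attempts; using expected mode"
        )
        return allocate_offspring(
            total_offspring, n_hosts, dist, mode="expected", max_clutch=max_clutch
        )
    raise ValueError(f"mode must be 'expected' or 'sampled', got {mode!r}")


def assign_sexes(
    clutch_sizes: list[int],
    p_female: float = 0.25,
    mode: str = "expected",
    seed: int | None = None,
) -> list[ClutchConfig]:
    """Assign female counts to clutches.

    The default ``p_female=0.25`` encodes the species' 3:1 male:female
    offspring sex ratio.  ``"expected"`` mode places
    ``round(p_female * total)`` females one per clutch in descending
    clutch-size order (ties broken by host order), wrapping around;
    ``"sampled"`` mode draws each clutch's female count binomially.
    """
    if not 0 <= p_female <= 1:
        raise ValueError(f"p_female must be in [0, 1], got {p_female}")
    if any(s < 1 for s in clutch_sizes):
        raise ValueError("clutch sizes must be >= 1")
    if not clutch_sizes:
        return []
    if mode == "expected":
        total = sum(clutch_sizes)
        n_females = int(np.floor(p_female * total + 0.5))
        females = [0] * len(clutch_sizes)
        # descending size, stable in host order
        order = sorted(range(len(clutch_sizes)), key=lambda i: (-clutch_sizes[i], i))
        while n_females > 0:
            placed = False
            for i in order:
                if n_females == 0:
                    break
                if females[i] < clutch_sizes[i]:
                    females[i] += 1
                    n_females -= 1
                    placed = True
            if not placed:  # every clutch saturated
                break
        return [ClutchConfig(s, f) for s, f in zip(clutch_sizes, females)]
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        return [
            ClutchConfig(s, int(rng.binomial(s, p_female))) for s in clutch_sizes
        ]
    raise ValueError(f"mode must be 'expected' or 'sampled', got {mode!r}")


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_f2(
    founder: FounderOutcome, model: FertilityModel | None = None
) -> ProjectionResult:
    """Project a founder's F2 fertility from her F1 clutch profile.

    Each emerged F1 female contributes ``fertility_of_clutch`` of her
    natal clutch size; clutches in fictitious hosts contribute only to
    the eggs-laid count (their larvae never complete development).
    """
    model = model if model is not None else FertilityModel()
    f2 = 0.0
    for h in founder.hosts:
        if h.parasitized and h.host_species == "native":
            f2 += h.clutch.females * fertility_of_clutch(h.clutch.size, model)
    females = founder.f1_females
    return ProjectionResult(
        founder_id=founder.founder_id,
        f1_eggs_laid=founder.eggs_laid,
        f1_fertility=founder.f1_fertility,
        f1_females=females,
        f2_fertility=f2,
        mean_offspring_fertility=(f2 / females) if females > 0 else None,
    )


def projections_table(
    founders: list[FounderOutcome], model: FertilityModel | None = None
) -> pd.DataFrame:
    """Per-founder :func:`project_f2` results as a tidy DataFrame."""
    rows = []
    for f in founders:
        r = project_f2(f, model)
        rows.append(
            {
                "founder_id": r.founder_id,
                "group": f.group,
                "f1_eggs_laid": r.f1_eggs_laid,
                "f1_fertility": r.f1_fertility,
                "f1_females": r.f1_females,
                "f2_fertility": r.f2_fertility,
                "mean_offspring_fertility": r.mean_offspring_fertility,
            }
        )
    return pd.DataFrame(rows)


def compare_scenarios(
    groups: dict[str, list[FounderOutcome]],
    model: FertilityModel | None = None,
) -> dict:
    """Compare two-generation fitness between labeled founder groups.

    Returns a dict with a per-group summary table and pairwise percent
    differences of the per-offspring F2 fertility mean, reported in both
    directions ((a-b)/b and (b-a)/a, x100).  The per-offspring mean of a
    group is the ratio of sums — total F2 fertility over total emerged
    females — which stays defined when individual founders have no
    emerged females; a group with zero emerged females overall is
    excluded from percent differences with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for name, founders in groups.items():
        if not founders:
            raise ValueError(f"group {name!r} is empty")
    model = model if model is not None else FertilityModel()

    summary_rows = {}
    for name, founders in groups.items():
        proj = [project_f2(f, model) for f in founders]
        clutch_sizes = [
            h.clutch.size
            for f in founders
            for h in f.hosts
            if h.parasitized and h.host_species == "native"
        ]
        tot_f2 = sum(p.f2_fertility for p in proj)
        tot_females = sum(p.f1_females for p in proj)
        per_offspring = tot_f2 / tot_females if tot_females > 0 else None
        if per_offspring is None:
            warnings.warn(
                f"group {name!r} has no emerged females; "
                "excluded from percent differences"
            )
        summary_rows[name] = {
            "n_founders": len(founders),
            "mean_f1_fertility": float(np.mean([p.f1_fertility for p in proj])),
            "mean_clutch_size": float(np.mean(clutch_sizes)) if clutch_sizes else None,
            "mean_f2_fertility": float(np.mean([p.f2_fertility for p in proj])),
            "mean_offspring_fertility": per_offspring,
        }

    pct = {}
    names = list(groups)
    for a in names:
        for b in names:
            if a == b:
                continue
            ma = summary_rows[a]["mean_offspring_fertility"]
            mb = summary_rows[b]["mean_offspring_fertility"]
            if ma is None or mb is None or mb == 0:
                continue
            pct[f"{a}_vs_{b}"] = (ma - mb) / mb * 100.0
    return {"groups": summary_rows, "percent_difference_per_offspring": pct}


def project_from_frequencies(
    freqs: dict[str, ClutchSizeDistribution],
    model: FertilityModel | None = None,
    p_female: float = 0.25,
    n_clutches: int = 1000,
) -> dict:
    """Two-generation comparison from per-group clutch-size frequencies.

    For each group, builds a representative cohort of ``n_clutches``
    clutches with sizes in the given frequencies (largest-remainder
    rounding), assigns sexes in expected mode class-by-class so each
    clutch-size class carries ``p_female`` of its offspring as females,
    projects F2 fertility, and compares groups.  This is the entry
    point for user-supplied empirical frequency tables (e.g. observed
    choice-test vs no-choice-test clutch-size distributions).
    """
    if n_clutches < 1:
        raise ValueError("n_clutches must be >= 1")
    groups: dict[str, list[FounderOutcome]] = {}
    for name, dist in freqs.items():
        counts = _largest_remainder(dist.probabilities() * n_clutches, n_clutches)
        configs: list[ClutchConfig] = []
        for size, count in zip(dist.sizes, counts):
            if count > 0:
                configs.extend(assign_sexes([size] * int(count), p_female, "expected"))
        hosts = [
            HostEggRecord("native", "usual_plant", True, cfg, True)
            for cfg in configs
        ]
        groups[name] = [FounderOutcome(f"{name}_cohort", name, hosts)]
    return compare_scenarios(groups, model)


# ---------------------------------------------------------------------------
# tidy CSV round-trip
# ---------------------------------------------------------------------------

def founders_to_table(founders: list[FounderOutcome]) -> pd.DataFrame:
    """One row per offered host egg, in the shared tidy schema."""
    rows = []
    for f in founders:
        for h in f.hosts:
            rows.append(
                {
                    "founder_id": f.founder_id,
                    "group": f.group,
                    "substrate": h.substrate,
                    "host_species": h.host_species,
                    "parasitized": h.parasitized,
                    "clutch_size": h.clutch.size if h.parasitized else pd.NA,
                    "n_females": h.clutch.females if h.parasitized else pd.NA,
                    "emerged": h.offspring_emerged,
                }
            )
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def table_to_founders(table: pd.DataFrame) -> list[FounderOutcome]:
    """Rebuild founder outcomes from a tidy per-host-egg table."""
    missing = [c for c in TIDY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"tidy table is missing columns: {missing}")
    founders = []
    for (fid, group), sub in table.groupby(["founder_id", "group"], sort=False):
        hosts = []
        for idx, row in sub.iterrows():
            parasitized = bool(row["parasitized"])
            clutch = None
            if parasitized:
                if pd.isna(row["clutch_size"]) or pd.isna(row["n_females"]):
                    raise ValueError(
                        f"row {idx}: parasitized egg lacks clutch_size/n_females"
                    )
                clutch = ClutchConfig(int(row["clutch_size"]), int(row["n_females"]))
            hosts.append(
                HostEggRecord(
                    host_species=str(row["host_species"]),
                    substrate=str(row["substrate"]),
                    parasitized=parasitized,
                    clutch=clutch,
                    offspring_emerged=bool(row["emerged"]),
                )
            )
        founders.append(FounderOutcome(fid, group, hosts))
    return founders


def write_founders_csv(founders: list[FounderOutcome], path) -> None:
    df = founders_to_table(founders)
    df = df.copy()
    for col in ("parasitized", "emerged"):
        df[col] = df[col].map({True: "true", False: "false"})
    df.to_csv(path, index=False)


def read_founders_csv(path) -> pd.DataFrame:
    """Read a tidy per-host-egg CSV, validating schema and dialect."""
    df = pd.read_csv(path)
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    for col in ("parasitized", "emerged"):
        vals = df[col]
        if vals.dtype == object:
            lowered = vals.astype(str).str.lower()
            bad = ~lowered.isin(["true", "false"])
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
                raise ValueError(
                    f"{path}: line {line}, column {col!r}: expected true/false, "
                    f"got {vals[bad].iloc[0]!r}"
                )
            df[col] = lowered == "true"
        else:
            df[col] = vals.astype(bool)
    return df
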