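"""Synthetic oviposition-experiment generator.

Emulates the three factorial designs of the host-switching experiments
with *Anaphes flavipes*: no-choice tests (12 native host eggs on a
single substrate), a choice test (4 eggs on each of three substrates in
one dish), and a fictitious-host test (6 native + 6 fictitious host
eggs on the fictitious host plant, against 6- and 12-egg native-only
controls).  The stochastic mechanism per founder is:

1. draw a founder (dish) random intercept ~ Normal(0, dish_sd) on the
   parasitism logit — the overdispersion a dish random factor absorbs;
2. parasitize each offered host egg independently with the
   logit-shifted substrate- and host-specific probability, while the
   pro-ovigenic egg budget lasts;
3. draw each clutch size from the substrate's clutch-size distribution,
   truncated to the remaining budget;
4. assign sexes binomially (default p_female = 0.25, the 3:1
   male:female ratio);
5. offspring emerge only from native hosts; for fictitious host eggs
   the *host beetle's* emergence is an independent Bernoulli (0.22 if
   parasitized, 0.94 for unparasitized controls — the reported rates).

The default parasitism probabilities and clutch-size presets are
package choices (clearly synthetic); only the two fictitious-host
emergence rates are empirical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .clutch import ClutchConfig, DEFAULT_MAX_CLUTCH
from .twogen import (
    SUBSTRATES,
    ClutchSizeDistribution,
    FounderOutcome,
    HostEggRecord,
    founders_to_table,
)

__all__ = [
    "ScenarioSpec",
    "GeneratorParams",
    "BUILTIN_SCENARIOS",
    "builtin_scenario",
    "generate_trials",
    "recover_params",
]

logger = logging.getLogger("flavipes")


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully parameterized experimental design.

    ``hosts_offered`` lists (substrate, host_species, count) triples;
    the order is the order eggs are encountered within a dish.
    ``exposure`` is metadata only (the assays used 8-hour exposures).
    """

    name: str
    n_founders: int
    hosts_offered: tuple[tuple[str, str, int], ...]
    exposure: str = "8h"

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        total = sum(c for _, _, c in self.hosts_offered)
        if total <= 0:
            raise ValueError("a scenario must offer at least one host egg")
        for sub, sp, c in self.hosts_offered:
            if sub not in SUBSTRATES:
                raise ValueError(f"unknown substrate {sub!r}")
            if sp not in ("native", "fictitious"):
                raise ValueError(f"unknown host species {sp!r}")
            if c < 0:
                raise ValueError("host counts must be non-negative")

    @property
    def total_hosts(self) -> int:
        return sum(c for _, _, c in self.hosts_offered)


#: the study's designs: three no-choice groups (n=20 each, 12 native eggs
#: on one substrate), the choice test (n=20, 4+4+4), and the fictitious-
#: host experiment (n=15 mixed, n=11 low density, n=19 high density)
BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "no_choice_usual": ScenarioSpec(
        "no_choice_usual", 20, (("usual_plant", "native", 12),)
    ),
    "no_choice_fictplant": ScenarioSpec(
        "no_choice_fictplant", 20, (("fictitious_plant", "native", 12),)
    ),
    "no_choice_control": ScenarioSpec(
        "no_choice_control", 20, (("control_paper", "native", 12),)
    ),
    "choice": ScenarioSpec(
        "choice",
        20,
        (
            ("usual_plant", "native", 4),
            ("fictitious_plant", "native", 4),
            ("control_paper", "native", 4),
        ),
    ),
    "fict_host_mix": ScenarioSpec(
        "fict_host_mix",
        15,
        (
            ("fictitious_plant", "native", 6),
            ("fictitious_plant", "fictitious", 6),
        ),
    ),
    "low_density": ScenarioSpec("low_density", 11, (("usual_plant", "native", 6),)),
    "high_density": ScenarioSpec("high_density", 19, (("usual_plant", "native", 12),)),
}


def builtin_scenario(name: str, n_founders: int | None = None) -> ScenarioSpec:
    """Look up a built-in design, optionally overriding the group size."""
    if name not in BUILTIN_SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; built-ins: {sorted(BUILTIN_SCENARIOS)}"
        )
    spec = BUILTIN_SCENARIOS[name]
    if n_founders is not None:
        spec = replace(spec, n_founders=n_founders)
    return spec


def _default_clutch_dists() -> dict[str, ClutchSizeDistribution]:
    # synthetic presets (the empirical frequency tables are not public);
    # mode at 2-3 on the usual plant, shifted toward smaller clutches on
    # the less-preferred substrates
    return {
        "usual_plant": ClutchSizeDistribution(
            {1: 0.12, 2: 0.30, 3: 0.30, 4: 0.16, 5: 0.08, 6: 0.03, 7: 0.01}
        ),
        "fictitious_plant": ClutchSizeDistribution(
            {1: 0.25, 2: 0.35, 3: 0.24, 4: 0.10, 5: 0.04, 6: 0.02}
        ),
        "control_paper": ClutchSizeDistribution(
            {1: 0.20, 2: 0.34, 3: 0.27, 4: 0.12, 5: 0.05, 6: 0.02}
        ),
    }


def _default_p_parasitize() -> dict[tuple[str, str], float]:
    # synthetic substrate x host-species acceptance probabilities
    return {
        ("usual_plant", "native"): 0.60,
        ("fictitious_plant", "native"): 0.45,
        ("control_paper", "native"): 0.50,
        ("usual_plant", "fictitious"): 0.35,
        ("fictitious_plant", "fictitious"): 0.35,
        ("control_paper", "fictitious"): 0.35,
    }


@dataclass
class GeneratorParams:
    """All knobs of the synthetic generator.

    ``dish_sd`` is the standard deviation of the founder-level Normal
    intercept on the parasitism logit (the dish random effect);
    ``egg_budget`` is the pro-ovigenic cap on total eggs per founder.
    The fictitious-host emergence probabilities default to the reported
    empirical rates (22% parasitized, 94% unparasitized control).
    """

    p_parasitize: dict[tuple[str, str], float] = field(
        default_factory=_default_p_parasitize
    )
    clutch_dist: dict[str, ClutchSizeDistribution] = field(
        default_factory=_default_clutch_dists
    )
    p_female: float = 0.25
    dish_sd: float = 0.5
    egg_budget: int = 32
    p_host_emerge_parasitized_fict: float = 0.22
    p_host_emerge_control_fict: float = 0.94
    max_clutch: int = DEFAULT_MAX_CLUTCH
    seed: int | None = None

    def validate(self) -> None:
        probs = list(self.p_parasitize.values()) + [
            self.p_female,
            self.p_host_emerge_parasitized_fict,
            self.p_host_emerge_control_fict,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.dish_sd < 0:
            raise ValueError("dish_sd must be >= 0")
        if self.egg_budget < 1:
            raise ValueError("egg_budget must be >= 1")
        if self.egg_budget < self.max_clutch:
            raise ValueError("egg_budget must be >= max_clutch")


def generate_trials(
    spec: ScenarioSpec,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> tuple[list[FounderOutcome], pd.DataFrame]:
    """Simulate one experimental group.

    Returns the founder outcomes and the tidy per-host-egg table (the
    table additionally carries ``host_emerged`` for fictitious host
    eggs: whether the *host beetle* itself emerged).  Reproducible given
    ``seed`` (falls back to ``params.seed``).
    """
    params = params if params is not None else GeneratorParams()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    founders: list[FounderOutcome] = []
    host_emergence_rows: list[dict] = []
    for i in range(spec.n_founders):
        fid = f"{spec.name}_{i + 1:03d}"
        intercept = rng.normal(0.0, params.dish_sd) if params.dish_sd > 0 else 0.0
        budget = params.egg_budget
        hosts: list[HostEggRecord] = []
        egg_index = 0
        for substrate, species, count in spec.hosts_offered:
            try:
                p = params.p_parasitize[(substrate, species)]
            except KeyError:
                raise KeyError(
                    f"p_parasitize lacks an entry for ({substrate!r}, {species!r})"
                ) from None
            dist = params.clutch_dist.get(substrate)
            if dist is None:
                raise KeyError(f"clutch_dist lacks an entry for {substrate!r}")
            for _ in range(count):
                egg_index += 1
                logit = special.logit(np.clip(p, 1e-12, 1 - 1e-12)) + intercept
                p_eff = float(special.expit(logit)) if params.dish_sd > 0 else p
                # budget below the distribution's smallest clutch: spent
                can_lay = budget >= min(dist.sizes)
                parasitized = can_lay and rng.random() < p_eff
                clutch = None
                if parasitized:
                    trunc = dist.truncated(min(budget, params.max_clutch))
                    size = int(trunc.sample(rng, 1)[0])
                    females = int(rng.binomial(size, params.p_female))
                    clutch = ClutchConfig(size, females)
                    budget -= size
                emerged = parasitized and species == "native"
                hosts.append(
                    HostEggRecord(
                        host_species=species,
                        substrate=substrate,
                        parasitized=parasitized,
                        clutch=clutch,
                        offspring_emerged=emerged,
                    )
                )
                if species == "fictitious":
                    p_host = (
                        params.p_host_emerge_parasitized_fict
                        if parasitized
                        else params.p_host_emerge_control_fict
                    )
                    host_emergence_rows.append(
                        {
                            "founder_id": fid,
                            "egg_index": egg_index,
                            "host_emerged": bool(rng.random() < p_host),
                        }
                    )
        founders.append(FounderOutcome(fid, spec.name, hosts))

    table = founders_to_table(founders)
    table["host_emerged"] = pd.NA
    if host_emergence_rows:
        em = pd.DataFrame(host_emergence_rows)
        # rows are emitted founder-by-founder in egg order, so align by
        # (founder_id, within-founder position)
        table["_egg_index"] = table.groupby("founder_id").cumcount() + 1
        em = em.set_index(["founder_id", "egg_index"])["host_emerged"]
        idx = pd.MultiIndex.from_arrays([table["founder_id"], table["_egg_index"]])
        table["host_emerged"] = em.reindex(idx).to_numpy()
        table = table.drop(columns="_egg_index")
    return founders, table


# ---------------------------------------------------------------------------
# generator self-validation: method-of-moments parameter recovery
# ---------------------------------------------------------------------------

def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def recover_params(table: pd.DataFrame) -> dict:
    """Method-of-moments estimates of the generating parameters.

    Returns per-(substrate, host_species) parasitism probabilities with
    Clopper–Pearson 95% CIs, per-substrate clutch-size means with
    t-based CIs, and the overall female proportion with its CP interval.
    Cells with zero exposure are reported as absent (None).
    """
    if table.empty:
        raise ValueError("cannot recover parameters from an empty table")

    out: dict = {"p_parasitize": {}, "clutch_mean": {}, "p_female": None}
    for (sub, sp), cell in table.groupby(["substrate", "host_species"]):
        n = len(cell)
        k = int(cell["parasitized"].sum())
        lo, hi = _clopper_pearson(k, n)
        out["p_parasitize"][(sub, sp)] = {
            "estimate": k / n,
            "ci_95": (lo, hi),
            "n": n,
        }

    par = table[table["parasitized"]]
    for sub, cell in par.groupby("substrate"):
        sizes = cell["clutch_size"].astype(float).to_numpy()
        n = len(sizes)
        mean = float(np.mean(sizes))
        if n >= 2 and np.std(sizes, ddof=1) > 0:
            se = float(np.std(sizes, ddof=1) / np.sqrt(n))
            t = stats.t.ppf(0.975, n - 1)
            ci = (mean - t * se, mean + t * se)
        else:
            ci = (mean, mean)
        out["clutch_mean"][sub] = {"estimate": mean, "ci_95": ci, "n": n}

    total_off = int(par["clutch_size"].sum()) if len(par) else 0
    total_fem = int(par["n_females"].sum()) if len(par) else 0
    if total_off > 0:
        lo, hi = _clopper_pearson(total_fem, total_off)
        out["p_female"] = {
            "estimate": total_fem / total_off,
            "ci_95": (lo, hi),
            "n": total_off,
        }
    return out
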