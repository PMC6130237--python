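"""Synthetic flower-visitation data with the structure the analysis assumes.

The generator emulates the statistical shape of a tropical visitation
census: two guilds of unequal richness (more visitors than plants),
right-skewed visit frequencies driven by lognormal species abundances, and
link structure arising from abundance products — which is exactly the
mechanism that produces nested webs.  A multi-habitat mode draws partially
overlapping species pools so that assemblage-similarity analyses have known
planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import InteractionMatrix, VisitRecord, WebValidationError

__all__ = ["SyntheticConfig", "generate_web", "generate_multihabitat", "fixtures"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mimic one habitat transect of a year-long census: 20 plant and
    40 visitor species (visitors richer, as in real visitation webs),
    lognormal abundances with sigma = 1 (a few dominant core species), and
    2,000 recorded visits.
    """

    R: int = 20
    C: int = 40
    abundance_sigma: float = 1.0
    n_visits: int = 2000
    structure: str = "neutral"  # neutral | uniform | modular
    n_blocks: int = 3  # modular mode only
    block_factor: float = 20.0  # within-block odds multiplier
    habitats: tuple[tuple[str, float], ...] | None = None  # (name, group overlap)
    groups: dict | None = None  # habitat name -> group id
    global_overlap: float = 0.0  # pool fraction shared by all habitats
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.R < 2 or self.C < 2:
            raise WebValidationError("need R, C >= 2")
        if self.n_visits < self.R + self.C:
            raise WebValidationError("n_visits must be >= R + C")
        if self.structure not in ("neutral", "uniform", "modular"):
            raise WebValidationError(f"unknown structure {self.structure!r}")
        for _name, ov in self.habitats or ():
            if not 0.0 <= ov <= 1.0:
                raise WebValidationError("overlap fractions must lie in [0, 1]")
        if not 0.0 <= self.global_overlap <= 1.0:
            raise WebValidationError("global_overlap must lie in [0, 1]")


def _cell_probabilities(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.structure == "uniform":
        p = np.ones((cfg.R, cfg.C))
    else:
        r = rng.lognormal(0.0, cfg.abundance_sigma, cfg.R)
        c = rng.lognormal(0.0, cfg.abundance_sigma, cfg.C)
        p = np.outer(r, c)
        if cfg.structure == "modular":
            rb = np.arange(cfg.R) % cfg.n_blocks
            cb = np.arange(cfg.C) % cfg.n_blocks
            p = p * np.where(rb[:, None] == cb[None, :], cfg.block_factor, 1.0)
    return p / p.sum()


def generate_web(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    plant_names: Sequence[str] | None = None,
    butterfly_names: Sequence[str] | None = None,
    habitat: str | None = None,
    keep_all_species: bool = False,
) -> InteractionMatrix:
    """Sample one quantitative web of ``cfg.n_visits`` visits.

    Cell probabilities follow the configured structure; the visit total is
    fixed (multinomial sampling, a fixed census effort).  Species that end
    up with zero visits are dropped so the web always validates — unless
    ``keep_all_species`` is set, in which case one visit per species is
    allocated first (to a partner drawn from its conditional distribution)
    and the remaining effort is sampled multinomially, guaranteeing the
    configured guild sizes survive.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p = _cell_probabilities(cfg, rng)
    plants = tuple(plant_names) if plant_names else tuple(f"P{i:03d}" for i in range(cfg.R))
    buts = tuple(butterfly_names) if butterfly_names else tuple(f"B{j:03d}" for j in range(cfg.C))
    counts = np.zeros((cfg.R, cfg.C), dtype=np.int64)
    n_free = cfg.n_visits
    if keep_all_species:
        for i in range(cfg.R):
            counts[i, rng.choice(cfg.C, p=p[i] / p[i].sum())] += 1
        for j in range(cfg.C):
            counts[rng.choice(cfg.R, p=p[:, j] / p[:, j].sum()), j] += 1
        n_free -= cfg.R + cfg.C
    counts += rng.multinomial(n_free, p.ravel()).reshape(cfg.R, cfg.C)
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    return InteractionMatrix(
        tuple(np.array(plants)[keep_r]),
        tuple(np.array(buts)[keep_c]),
        counts[np.ix_(keep_r, keep_c)],
        habitat=habitat,
    )


def _habitat_pool(
    names: Sequence[str],
    global_core: Sequence[str],
    group_core: Sequence[str],
    unique: Sequence[str],
    n_global: int,
    n_group: int,
    total: int,
) -> tuple[str, ...]:
    pool = list(global_core[:n_global]) + list(group_core[:n_group])
    pool += list(unique[: total - len(pool)])
    return tuple(pool)


def generate_multihabitat(cfg: SyntheticConfig) -> list[VisitRecord]:
    """Long-format census records for several habitats with planted overlap.

    Each habitat's species pool (both guilds) is composed of a fraction
    ``cfg.global_overlap`` drawn from a community-wide core, a fraction
    given by the habitat's own overlap value drawn from its *group's* core
    (groups via ``cfg.groups``; ungrouped habitats form singletons), and
    unique species for the remainder.  Habitats in the same group therefore
    share ``global_overlap + overlap`` of their pools; habitats in
    different groups share only the global core.
    """
    if not cfg.habitats or len(cfg.habitats) < 2:
        raise WebValidationError("need at least two habitats")
    rng = np.random.default_rng(cfg.seed)
    groups = dict(cfg.groups or {})
    for name, _ in cfg.habitats:
        groups.setdefault(name, f"_solo_{name}")
    for name, ov in cfg.habitats:
        if cfg.global_overlap + ov > 1.0 + 1e-9:
            raise WebValidationError(
                f"habitat {name!r}: global_overlap + overlap exceeds 1"
            )

    def build_pools(prefix: str, n: int) -> dict[str, tuple[str, ...]]:
        counter = iter(range(10**6))
        fresh = lambda: f"{prefix}{next(counter):04d}"
        n_global = round(cfg.global_overlap * n)
        global_core = [fresh() for _ in range(n_global)]
        group_cores: dict[str, list[str]] = {}
        pools = {}
        for name, ov in cfg.habitats:
            g = groups[name]
            n_group = round(ov * n)
            core = group_cores.setdefault(g, [])
            while len(core) < n_group:
                core.append(fresh())
            unique = [fresh() for _ in range(n - n_global - n_group)]
            pools[name] = tuple(global_core + core[:n_group] + unique)
        return pools

    plant_pools = build_pools("P", cfg.R)
    but_pools = build_pools("B", cfg.C)

    records: list[VisitRecord] = []
    for name, _ov in cfg.habitats:
        web = generate_web(
            cfg,
            rng=rng,
            plant_names=plant_pools[name],
            butterfly_names=but_pools[name],
            habitat=name,
        )
        for i, p in enumerate(web.row_labels):
            for j, b in enumerate(web.col_labels):
                c = int(web.counts[i, j])
                if c:
                    records.append(VisitRecord(name, p, b, c))
    return records


def fixtures() -> dict:
    """Named binary matrices with analytically known NODF."""

    def perfectly_nested(n: int) -> np.ndarray:
        return np.triu(np.ones((n, n), dtype=np.int64))[:, ::-1]

    def checkerboard(n: int) -> np.ndarray:
        i, j = np.indices((n, n))
        return ((i + j) % 2 == 0).astype(np.int64)

    def full(n: int) -> np.ndarray:
        return np.ones((n, n), dtype=np.int64)

    def modular_blocks(k: int, size: int) -> np.ndarray:
        return np.kron(np.eye(k, dtype=np.int64), np.ones((size, size), dtype=np.int64))

    return {
        "perfectly_nested": perfectly_nested,
        "checkerboard": checkerboard,
        "full": full,
        "modular_blocks": modular_blocks,
    }
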