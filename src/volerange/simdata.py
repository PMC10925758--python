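"""Synthetic semi-natural enclosure generator.

Generates everything the downstream pipeline consumes — agents with planted
mating tactics, radiotracking fixes, and diploid microsatellite genotypes for
adults and embryos — so the full analysis is exercisable with no field data.

Movement model: each animal's fixes are drawn from an isotropic bivariate
normal mixture over its nest centre(s), truncated to the enclosure rectangle
by resampling. Residents (and females) use a single centre shared with their
partner; wanderers mix uniformly over several centres with a larger
dispersion. Lesioned wanderers have their dispersion and centre count shrunk
by ``lesion_wanderer_shrink``, which is the generator's only lesion effect.

Genetics: per-locus allele frequencies are Dirichlet draws; adults are
Hardy-Weinberg draws from those frequencies; embryos receive one allele
uniformly from the mother's pair and one from the true sire's pair
(Mendelian transmission, no mutation). Extra-pair sires are sampled with
weight proportional to the overlap of the true nest-centre distributions.

One master seed drives everything through deterministically spawned
substreams, so a config (seed included) reproduces its dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig

__all__ = [
    "AgentSpec",
    "generate_population",
    "simulate_fixes",
    "simulate_matings_and_genotypes",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
    "insufficient_animals",
    "locus_columns",
]

ARTIFACT_VERSION = 1


class ConfigError(ValueError):
    """Raised when a configuration cannot produce a valid population."""


@dataclass
class AgentSpec:
    """Planted ground truth for one simulated animal."""

    animal_id: str
    enclosure_id: str
    sex: str                      # 'M' or 'F'
    surgery: str                  # 'sham', 'lesion' or 'none' (females)
    true_tactic: str | None       # males: 'resident' / 'wanderer'; females None
    nest_centers: list[tuple[float, float]] = field(default_factory=list)
    partner_id: str | None = None
    sigma: float | None = None      # movement dispersion, set at generation


def _streams(config: SimConfig) -> dict[str, np.random.SeedSequence]:
    """Named per-stage substreams of the master seed."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(3)
    return {"population": children[0], "fixes": children[1],
            "genetics": children[2]}


def _sample_separated_points(rng: np.random.Generator, n: int,
                             width: float, height: float,
                             min_sep: float, max_tries: int = 10_000
                             ) -> np.ndarray:
    """Uniform points in the rectangle with pairwise separation >= min_sep."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        p = rng.uniform([0.0, 0.0], [width, height])
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
        tries += 1
        if tries > max_tries:
            raise ConfigError(
                f"could not place {n} nests >= {min_sep} m apart in a "
                f"{width} x {height} m arena")
    return np.asarray(pts)


def generate_population(config: SimConfig) -> list[AgentSpec]:
    """Draw agents for every enclosure with planted tactics and nests.

    Each male is independently a resident with probability ``p_resident``;
    residents are paired one-to-one with distinct females and share that
    female's nest centre. Nest centres (one per female) are uniform in the
    arena with a minimum separation; wanderer centres are uniform without a
    separation constraint. If an enclosure draws more residents than it has
    females the tactic draws are regenerated (bounded retries).
    """
    rng = np.random.default_rng(_streams(config)["population"])
    agents: list[AgentSpec] = []
    n_f = config.females_per_enclosure
    n_m = config.males_per_enclosure

    for e in range(1, config.n_enclosures + 1):
        enc = f"E{e}"
        # tactic draws, retried if residents outnumber females
        for _ in range(100):
            tactics = rng.random(n_m) < config.p_resident
            if tactics.sum() <= n_f:
                break
        else:
            raise ConfigError(
                f"enclosure {enc}: more resident males than females after "
                "bounded retries; lower p_resident or add females")

        nests = _sample_separated_points(
            rng, n_f, config.grid_width_m, config.grid_height_m,
            config.min_nest_separation_m)

        females = [
            AgentSpec(animal_id=f"{enc}F{j + 1:02d}", enclosure_id=enc,
                      sex="F", surgery="none", true_tactic=None,
                      nest_centers=[tuple(nests[j])])
            for j in range(n_f)
        ]
        for f_agent in females:
            f_agent.sigma = config.resident_sigma_m

        surgeries = (["lesion"] * config.lesion_males
                     + ["sham"] * config.sham_males)
        # residents claim distinct females in a random order
        available = list(rng.permutation(n_f))
        males: list[AgentSpec] = []
        for i in range(n_m):
            m = AgentSpec(animal_id=f"{enc}M{i + 1:02d}", enclosure_id=enc,
                          sex="M", surgery=surgeries[i],
                          true_tactic="resident" if tactics[i] else "wanderer")
            if tactics[i]:
                j = int(available.pop())
                partner = females[j]
                m.partner_id = partner.animal_id
                partner.partner_id = m.animal_id
                m.nest_centers = list(partner.nest_centers)
                m.sigma = config.resident_sigma_m
            else:
                shrink = (config.lesion_wanderer_shrink
                          if surgeries[i] == "lesion" else 1.0)
                n_centers = max(1, round(config.n_wanderer_centers * shrink))
                centers = rng.uniform(
                    [0.0, 0.0],
                    [config.grid_width_m, config.grid_height_m],
                    size=(n_centers, 2))
                m.nest_centers = [tuple(c) for c in centers]
                m.sigma = config.wanderer_sigma_m * shrink
            males.append(m)

        agents.extend(females)
        agents.extend(males)
    return agents


def _session_labels(fixes_per_day: int) -> list[str]:
    if fixes_per_day == 2:
        return ["AM", "PM"]
    return [f"S{i + 1}" for i in range(fixes_per_day)]


def _truncated_normal_fixes(rng: np.random.Generator, centers: np.ndarray,
                            sigma: float, n: int, width: float,
                            height: float) -> np.ndarray:
    """n fixes around uniformly chosen centres, resampled into the arena."""
    out = np.empty((n, 2))
    pending = np.arange(n)
    which = rng.integers(0, len(centers), size=n)
    while pending.size:
        draw = centers[which[pending]] + rng.normal(
            0.0, sigma, size=(pending.size, 2))
        ok = ((draw[:, 0] >= 0) & (draw[:, 0] <= width)
              & (draw[:, 1] >= 0) & (draw[:, 1] <= height))
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
    return out


def simulate_fixes(agents: list[AgentSpec], config: SimConfig) -> pd.DataFrame:
    """Simulate the radiotracking table: one row per realised fix.

    Every animal has ``days * fixes_per_day`` slots; each slot is dropped
    independently with probability ``fix_loss_rate`` (missing fixes are
    absent rows, not blanks). Columns: enclosure_id, animal_id, sex,
    surgery, day (1-based), session, x_m, y_m; sorted by animal, day,
    session order.
    """
    rng = np.random.default_rng(_streams(config)["fixes"])
    sessions = _session_labels(config.fixes_per_day)
    n_slots = config.fixes_per_animal
    rows: list[pd.DataFrame] = []
    for a in sorted(agents, key=lambda a: a.animal_id):
        sigma = a.sigma
        centers = np.asarray(a.nest_centers)
        if sigma == 0:
            xy = centers[rng.integers(0, len(centers), n_slots)]
        else:
            xy = _truncated_normal_fixes(
                rng, centers, sigma, n_slots,
                config.grid_width_m, config.grid_height_m)
        if config.snap_to_metre:
            xy = np.round(xy)
        keep = rng.random(n_slots) >= config.fix_loss_rate
        day = np.repeat(np.arange(1, config.days + 1), config.fixes_per_day)
        sess = np.tile(sessions, config.days)
        rows.append(pd.DataFrame({
            "enclosure_id": a.enclosure_id,
            "animal_id": a.animal_id,
            "sex": a.sex,
            "surgery": a.surgery,
            "day": day[keep],
            "session": sess[keep],
            "x_m": xy[keep, 0],
            "y_m": xy[keep, 1],
        }))
    fixes = pd.concat(rows, ignore_index=True)
    order = {s: i for i, s in enumerate(sessions)}
    fixes = fixes.sort_values(
        ["animal_id", "day", "session"],
        key=lambda c: c.map(order) if c.name == "session" else c,
    ).reset_index(drop=True)
    return fixes


def insufficient_animals(fixes: pd.DataFrame, min_fixes: int = 28) -> list[str]:
    """Animals with fewer than ``min_fixes`` realised fixes (flagged, kept)."""
    counts = fixes.groupby("animal_id").size()
    return sorted(counts.index[counts < min_fixes])


def locus_columns(n_loci: int) -> list[str]:
    cols = []
    for i in range(1, n_loci + 1):
        cols += [f"locus{i:02d}_a", f"locus{i:02d}_b"]
    return cols


def _nest_overlap_weight(male: AgentSpec, female: AgentSpec) -> float:
    """Overlap of the two agents' true fix distributions (Gaussian product
    mass), summed over the male's centres."""
    sf = female.sigma
    sm = male.sigma
    var = sf * sf + sm * sm
    fx, fy = female.nest_centers[0]
    w = 0.0
    for (mx, my) in male.nest_centers:
        d2 = (fx - mx) ** 2 + (fy - my) ** 2
        w += np.exp(-d2 / (2.0 * var)) / var
    return w


def simulate_matings_and_genotypes(
        agents: list[AgentSpec], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate litters and diploid genotypes at ``n_loci`` microsatellites.

    Returns ``(adults, embryos)``. Adults carry Hardy-Weinberg genotypes
    from per-locus Dirichlet allele frequencies. Every female carries a
    litter (size 1 + Poisson(litter_size_mean - 1)). A paired female's
    litter is sired by her partner except, with probability ``epf_rate``,
    one or more embryos are sired by a non-partner male sampled with weight
    proportional to nest-distribution overlap; an unpaired female's litter
    is sired by the overlap-weighted male. Embryo inheritance is Mendelian;
    ``genotype_dropout`` knocks out individual allele calls at random.
    """
    rng = np.random.default_rng(_streams(config)["genetics"])
    k = config.alleles_per_locus
    freqs = rng.dirichlet(
        np.full(k, config.dirichlet_concentration), size=config.n_loci)

    by_enc: dict[str, list[AgentSpec]] = {}
    for a in agents:
        by_enc.setdefault(a.enclosure_id, []).append(a)

    adults = sorted(agents, key=lambda a: a.animal_id)
    alleles = np.arange(1, k + 1)
    geno = {a.animal_id: np.stack([
        rng.choice(alleles, size=2, p=freqs[l]) for l in range(config.n_loci)
    ]) for a in adults}

    embryo_rows: list[dict] = []
    for enc in sorted(by_enc):
        members = by_enc[enc]
        females = [a for a in members if a.sex == "F"]
        males = [a for a in members if a.sex == "M"]
        by_id = {a.animal_id: a for a in members}
        for f_agent in sorted(females, key=lambda a: a.animal_id):
            litter = 1 + rng.poisson(max(config.litter_size_mean - 1.0, 0.0))
            if f_agent.partner_id is not None:
                sires = [f_agent.partner_id] * litter
                others = [m for m in males
                          if m.animal_id != f_agent.partner_id]
                if others and rng.random() < config.epf_rate:
                    w = np.array([_nest_overlap_weight(m, f_agent)
                                  for m in others])
                    p = w / w.sum() if w.sum() > 0 else np.full(len(w),
                                                               1 / len(w))
                    ep_sire = others[rng.choice(len(others), p=p)].animal_id
                    n_ep = 1 + rng.binomial(litter - 1, 0.3)
                    for idx in rng.choice(litter, size=n_ep, replace=False):
                        sires[idx] = ep_sire
            else:
                # unpaired female: proximity-weighted sire. A paired male
                # siring here is an extra-pair sire for HIS pair, so paired
                # males are only eligible with probability epf_rate.
                pool = males
                if rng.random() >= config.epf_rate:
                    unpaired = [m for m in males if m.partner_id is None]
                    if unpaired:
                        pool = unpaired
                w = np.array([_nest_overlap_weight(m, f_agent) for m in pool])
                p = w / w.sum() if w.sum() > 0 else np.full(len(w), 1 / len(w))
                sire = pool[rng.choice(len(pool), p=p)].animal_id
                sires = [sire] * litter
            for j, sire_id in enumerate(sires):
                gm = geno[f_agent.animal_id]
                gs = geno[sire_id]
                maternal = gm[np.arange(config.n_loci),
                              rng.integers(0, 2, config.n_loci)]
                paternal = gs[np.arange(config.n_loci),
                              rng.integers(0, 2, config.n_loci)]
                embryo_rows.append({
                    "embryo_id": f"{f_agent.animal_id}X{j + 1:02d}",
                    "enclosure_id": enc,
                    "mother_id": f_agent.animal_id,
                    "true_sire_id": sire_id,
                    "_geno": np.stack([maternal, paternal], axis=1),
                })

    def _geno_frame(ids_meta: list[dict], genos: list[np.ndarray]) -> pd.DataFrame:
        mat = np.stack([g.reshape(-1) for g in genos]).astype(float)
        if config.genotype_dropout > 0:
            drop = rng.random(mat.shape) < config.genotype_dropout
            mat[drop] = np.nan
        df = pd.DataFrame(mat, columns=locus_columns(config.n_loci))
        meta = pd.DataFrame(ids_meta)
        return pd.concat([meta, df.astype("Int64")], axis=1)

    adults_df = _geno_frame(
        [{"animal_id": a.animal_id, "enclosure_id": a.enclosure_id,
          "sex": a.sex, "surgery": a.surgery} for a in adults],
        [geno[a.animal_id] for a in adults])
    embryos_df = _geno_frame(
        [{k2: r[k2] for k2 in
          ("embryo_id", "enclosure_id", "mother_id", "true_sire_id")}
         for r in embryo_rows],
        [r["_geno"] for r in embryo_rows])
    return adults_df, embryos_df


def simulate_dataset(config: SimConfig
                     ) -> tuple[list[AgentSpec], pd.DataFrame,
                                pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: agents, fixes, adult and embryo genotypes."""
    agents = generate_population(config)
    fixes = simulate_fixes(agents, config)
    adults, embryos = simulate_matings_and_genotypes(agents, config)
    return agents, fixes, adults, embryos


def write_dataset(fixes: pd.DataFrame, adults: pd.DataFrame,
                  embryos: pd.DataFrame, path: str | Path,
                  config: SimConfig | None = None) -> None:
    """Write fixes.csv / adults.csv / embryos.csv plus a manifest echoing the
    config and seed, so a dataset regenerates byte-identically."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    fixes.to_csv(out / "fixes.csv", index=False)
    adults.to_csv(out / "adults.csv", index=False)
    embryos.to_csv(out / "embryos.csv", index=False)
    manifest: dict = {"artifact_version": ARTIFACT_VERSION}
    if config is not None:
        manifest["config"] = config.to_dict()
        manifest["seed"] = config.seed
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest,
                                                      sort_keys=True))


def read_dataset(path: str | Path
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back a dataset directory written by :func:`write_dataset`."""
    p = Path(path)
    fixes = pd.read_csv(p / "fixes.csv")

    def _read_geno(f: Path) -> pd.DataFrame:
        df = pd.read_csv(f)
        loci = [c for c in df.columns if c.startswith("locus")]
        df[loci] = df[loci].astype("Int64")
        return df

    adults = _read_geno(p / "adults.csv")
    embryos = _read_geno(p / "embryos.csv")
    return fixes, adults, embryos
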