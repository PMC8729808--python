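"""Synthetic β-value and MSP Ct cohorts with planted marker complementarity.

The generators emulate the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without external downloads:

* **β cohorts** (450k-style tissue data): each sample draws a tumor
  location, then a latent methylation state per gene (Bernoulli with
  group/location-specific probability), then per-probe β values from a
  truncated-normal emission for that state.  An explicit anchor–complement
  dependence (probability the complement gene is methylated given the
  anchor is not) plants the complementarity the screen is meant to recover.
* **Ct cohorts** (stool/tissue MSP data): the reference gene ACTB draws a
  group-specific Ct (cancer stools shed more epithelial cells, so mean
  Ct(CRC) < Ct(adenoma) < Ct(normal)); methylated targets amplify at
  ACTB + ΔCt, unmethylated targets mostly fail to amplify within the
  45-cycle run.

All draws flow from a single explicit seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import (
    BetaMatrix,
    CtTable,
    Group,
    Location,
    MAX_CYCLES,
    NO_AMP,
    ProbeAnnotation,
    REFERENCE_GENE,
    SDC2_ISLAND_PROBES,
    SampleRecord,
    ValidationError,
)
from .reference_tables import STOOL_COMPLEMENT_COUNTS, STOOL_SUBSITE_SENSITIVITY

__all__ = [
    "GeneBetaSpec",
    "BetaSimConfig",
    "CtSimConfig",
    "simulate_beta_cohort",
    "simulate_ct_cohort",
    "beta_annotation",
    "default_paper_like_config",
    "planted_screen_config",
]

Prob = float | Mapping[Location, float]
GroupProb = float | Mapping[Group, Prob]


def _resolve(p: GroupProb, group: Group, location: Location) -> float:
    """Resolve a (possibly group- and location-stratified) probability."""
    if isinstance(p, Mapping):
        p = p[group]  # type: ignore[index]
    if isinstance(p, Mapping):
        if location in p:
            p = p[location]
        elif "default" in p:  # type: ignore[operator]
            p = p["default"]  # type: ignore[index]
        else:
            raise ValidationError(f"no probability for location {location!r}")
    v = float(p)  # type: ignore[arg-type]
    if not 0.0 <= v <= 1.0:
        raise ValidationError(f"probability {v} outside [0,1]")
    return v


def _check_dist(dist: Mapping[Location, float], what: str) -> None:
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{what} sums to {total}, not 1")
    if any(v < 0 for v in dist.values()):
        raise ValidationError(f"{what} has a negative weight")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return scipy.stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                     random_state=rng)


# --------------------------------------------------------------------------
# β cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneBetaSpec:
    """Per-gene latent-state and β-emission parameters.

    ``meth_frac`` is the probability a sample of a given group (and
    optionally location) is methylated at this gene; for the configured
    complement gene it is conditional on the anchor being methylated (the
    anchor-unmethylated branch uses the dependence parameter of the cohort
    config).  Emissions are truncated normals on [0, 1].
    """

    gene: str
    meth_frac: GroupProb
    meth_mean: float = 0.492
    meth_sd: float = 0.178
    unmeth_mean: float = 0.067
    unmeth_sd: float = 0.018
    island_id: str = ""

    @property
    def island(self) -> str:
        return self.island_id or f"{self.gene}_island"


@dataclass
class BetaSimConfig:
    """Configuration of a simulated 450k-style β cohort."""

    n_case: int
    n_control: int
    n_adenoma: int
    genes: list[GeneBetaSpec]
    location_distribution: dict[Location, float]
    anchor_gene: str = "SDC2"
    complement_gene: str | None = "TFPI2"
    #: P(complement methylated | anchor unmethylated), per group/location.
    complement_given_anchor_neg: GroupProb = 0.88
    probes_per_island: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.n_case + self.n_control + self.n_adenoma <= 0:
            raise ValidationError("cohort has zero samples")
        if self.probes_per_island < 1:
            raise ValidationError("probes_per_island must be >= 1")
        names = [g.gene for g in self.genes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene in BetaSimConfig")
        if self.anchor_gene not in names:
            raise ValidationError(f"anchor gene {self.anchor_gene!r} not in gene list")
        if self.complement_gene is not None and self.complement_gene not in names:
            raise ValidationError(f"complement gene {self.complement_gene!r} not in gene list")
        _check_dist(self.location_distribution, "location_distribution")
        for g in self.genes:
            for m, s in ((g.meth_mean, g.meth_sd), (g.unmeth_mean, g.unmeth_sd)):
                if not (0.0 <= m <= 1.0) or s <= 0:
                    raise ValidationError(f"bad emission parameters for {g.gene}")


def _sample_frame(n_case: int, n_adenoma: int, n_control: int,
                  rng: np.random.Generator,
                  loc_dist: Mapping[Group, Mapping[Location, float]] | Mapping[Location, float],
                  cohort: str) -> list[SampleRecord]:
    records = []
    for group, n, prefix in (
        (Group.CRC, n_case, "CRC"),
        (Group.adenoma, n_adenoma, "ADE"),
        (Group.normal, n_control, "NRM"),
    ):
        if n == 0:
            continue
        dist = loc_dist[group] if isinstance(next(iter(loc_dist)), Group) else loc_dist  # type: ignore[arg-type]
        locs = list(dist.keys())  # type: ignore[union-attr]
        probs = np.array([dist[l] for l in locs], dtype=float)  # type: ignore[index]
        draws = rng.choice(len(locs), size=n, p=probs / probs.sum())
        for i in range(n):
            records.append(
                SampleRecord(
                    sample_id=f"{prefix}_{i + 1:04d}",
                    group=group,
                    location=locs[draws[i]],
                    cohort=cohort,
                )
            )
    return records


def _draw_states(records: list[SampleRecord], rng: np.random.Generator,
                 anchor_gene: str,
                 complement_gene: str | None,
                 gene_probs: Mapping[str, GroupProb],
                 complement_given_anchor_neg: GroupProb) -> pd.DataFrame:
    """Latent methylation state per sample × gene.

    The anchor is drawn first; the complement is drawn conditionally on the
    anchor's state (the dependence that creates complementarity); all other
    genes are independent given group and location.
    """
    genes = list(gene_probs)
    n = len(records)
    cols = {g: np.zeros(n, dtype=bool) for g in genes}
    for i, r in enumerate(records):
        anchor = rng.random() < _resolve(gene_probs[anchor_gene], r.group, r.location)
        cols[anchor_gene][i] = anchor
        for g in genes:
            if g == anchor_gene:
                continue
            if g == complement_gene and not anchor:
                p = _resolve(complement_given_anchor_neg, r.group, r.location)
            else:
                p = _resolve(gene_probs[g], r.group, r.location)
            cols[g][i] = rng.random() < p
    return pd.DataFrame(cols, index=[r.sample_id for r in records], columns=genes)


def beta_annotation(config: BetaSimConfig) -> ProbeAnnotation:
    """Probe → gene/island annotation matching a simulated β matrix.

    The anchor gene reuses the canonical 12-probe SDC2 island ids when the
    configuration asks for 12 probes; other islands get synthetic probe ids.
    """
    rows = []
    for g in config.genes:
        for i in range(config.probes_per_island):
            if (g.gene == "SDC2" and config.probes_per_island == len(SDC2_ISLAND_PROBES)):
                pid = SDC2_ISLAND_PROBES[i]
            else:
                pid = f"{g.island}_p{i + 1:02d}"
            rows.append({"probe_id": pid, "gene": g.gene, "island_id": g.island})
    return ProbeAnnotation(pd.DataFrame(rows))


def simulate_beta_cohort(
    config: BetaSimConfig, seed: int | None = None
) -> tuple[BetaMatrix, list[SampleRecord], pd.DataFrame]:
    """Simulate a β cohort; returns (matrix, records, truth states).

    Deterministic given the seed (``seed`` overrides ``config.seed``).
    The truth table is a sample × gene boolean DataFrame of latent states.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = _sample_frame(config.n_case, config.n_adenoma, config.n_control,
                            rng, config.location_distribution, cohort="sim_beta")
    gene_probs = {g.gene: g.meth_frac for g in config.genes}
    states = _draw_states(records, rng, config.anchor_gene, config.complement_gene,
                          gene_probs, config.complement_given_anchor_neg)

    annotation = beta_annotation(config)
    sample_ids = [r.sample_id for r in records]
    P = config.probes_per_island
    blocks = []
    for g in config.genes:
        meth = states[g.gene].to_numpy()
        block = np.empty((P, len(sample_ids)))
        for state, mean, sd in ((True, g.meth_mean, g.meth_sd),
                                (False, g.unmeth_mean, g.unmeth_sd)):
            idx = np.where(meth == state)[0]
            if idx.size:
                draws = _truncnorm(rng, mean, sd, 0.0, 1.0, size=P * idx.size)
                block[:, idx] = draws.reshape(P, idx.size)
        blocks.append(block)
    values = pd.DataFrame(
        np.vstack(blocks), index=annotation.probe_ids, columns=sample_ids
    )
    return BetaMatrix(values), records, states


# --------------------------------------------------------------------------
# Ct cohorts
# --------------------------------------------------------------------------

@dataclass
class CtSimConfig:
    """Configuration of a simulated MSP Ct cohort (stool-style by default).

    ``actb_ct`` gives the reference-gene Ct distribution per group; means
    must be ordered CRC < adenoma < normal (cancer stools carry the most
    exfoliated human cells).  Methylated targets amplify at
    ACTB Ct + N(ΔCt mean, sd), censored to NO_AMP past the 45-cycle run;
    unmethylated targets are NO_AMP with probability ``no_amp_prob``, else
    amplify late (uniform above the 38-cycle positivity cutoff).
    """

    n_per_group: dict[Group, int]
    actb_ct: dict[Group, tuple[float, float]]
    location_distribution: dict[Group, dict[Location, float]]
    anchor_meth_prob: GroupProb
    complement_meth_prob: GroupProb  # given anchor methylated
    complement_given_anchor_neg: GroupProb
    delta_ct: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"SDC2": (5.0, 1.8), "TFPI2": (5.5, 1.8)}
    )
    anchor_gene: str = "SDC2"
    complement_gene: str = "TFPI2"
    no_amp_prob: float = 0.97
    unmeth_ct_range: tuple[float, float] = (38.05, 45.0)
    max_cycles: float = MAX_CYCLES
    calibrator_actb_ct: float = 28.0
    calibrator_delta_ct: dict[str, float] = field(
        default_factory=lambda: {"SDC2": 0.0, "TFPI2": 0.0}
    )
    seed: int = 0

    def validate(self) -> None:
        if sum(self.n_per_group.values()) <= 0:
            raise ValidationError("cohort has zero samples")
        present = [g for g in (Group.CRC, Group.adenoma, Group.normal)
                   if self.n_per_group.get(g, 0) > 0]
        means = [self.actb_ct[g][0] for g in present]
        if means != sorted(means):
            raise ValidationError(
                "ACTB Ct means must satisfy mean(CRC) < mean(adenoma) < mean(normal)"
            )
        for g, dist in self.location_distribution.items():
            _check_dist(dist, f"location_distribution[{g}]")
        if not 0.0 <= self.no_amp_prob <= 1.0:
            raise ValidationError("no_amp_prob outside [0,1]")
        lo, hi = self.unmeth_ct_range
        if not (0 < lo < hi <= self.max_cycles):
            raise ValidationError("unmeth_ct_range outside (0, max_cycles]")

    @property
    def target_genes(self) -> tuple[str, str]:
        return (self.anchor_gene, self.complement_gene)


def simulate_ct_cohort(
    config: CtSimConfig, seed: int | None = None
) -> tuple[CtTable, list[SampleRecord], pd.DataFrame]:
    """Simulate an MSP cohort; returns (Ct table, records, truth states).

    Deterministic given the seed.  Calibrator (positive-control) and
    negative-control wells are emitted alongside the per-sample rows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = _sample_frame(
        config.n_per_group.get(Group.CRC, 0),
        config.n_per_group.get(Group.adenoma, 0),
        config.n_per_group.get(Group.normal, 0),
        rng, config.location_distribution, cohort="sim_ct",
    )
    gene_probs = {
        config.anchor_gene: config.anchor_meth_prob,
        config.complement_gene: config.complement_meth_prob,
    }
    states = _draw_states(records, rng, config.anchor_gene, config.complement_gene,
                          gene_probs, config.complement_given_anchor_neg)

    rows = []
    for r in records:
        mean, sd = config.actb_ct[r.group]
        actb = float(_truncnorm(rng, mean, sd, 0.0, config.max_cycles, size=1)[0])
        rows.append({"sample_id": r.sample_id, "gene": REFERENCE_GENE, "ct": actb})
        for gene in config.target_genes:
            if states.loc[r.sample_id, gene]:
                dmean, dsd = config.delta_ct[gene]
                ct = actb + rng.normal(dmean, dsd)
                ct_val = np.nan if ct > config.max_cycles else max(ct, 1e-3)
            else:
                if rng.random() < config.no_amp_prob:
                    ct_val = np.nan
                else:
                    lo, hi = config.unmeth_ct_range
                    ct_val = rng.uniform(lo, hi)
            rows.append({"sample_id": r.sample_id, "gene": gene, "ct": ct_val})

    calibrator = {REFERENCE_GENE: config.calibrator_actb_ct}
    for gene in config.target_genes:
        calibrator[gene] = config.calibrator_actb_ct + config.calibrator_delta_ct[gene]
    negative_control: dict[str, object] = {g: NO_AMP for g in config.target_genes}
    negative_control[REFERENCE_GENE] = 30.0
    table = CtTable(
        measurements=pd.DataFrame(rows),
        calibrator=calibrator,
        negative_control=negative_control,  # type: ignore[arg-type]
    )
    return table, records, states


# --------------------------------------------------------------------------
# Defaults calibrated to the published cohorts
# --------------------------------------------------------------------------

def _rate_map(group: Group) -> dict[Location, float]:
    """Published complement rates (positive/total) per location, as fractions."""
    return {
        loc: pos / (pos + neg)
        for loc, (pos, neg) in STOOL_COMPLEMENT_COUNTS[group].items()
    }


def default_paper_like_config() -> tuple[BetaSimConfig, CtSimConfig]:
    """Defaults emulating the published discovery and stool cohorts.

    The β config mirrors the 450k discovery cohort (391 CRC / 45 normal
    tissues; anchor peaks 0.067/0.492, complement peaks 0.161/0.558; anchor
    positivity per subsite shaped after the published per-site single-marker
    sensitivities; anchor→complement dependence 0.88).  The Ct config mirrors
    the stool cohort (289 CRC / 190 adenoma / 217 normal) with per-location
    anchor positivity and complement-given-anchor-negative rates taken from
    the published subsite tables; expected single/dual cancer sensitivities
    are ≈ 0.87 / 0.94 (approximate — binomial noise applies at cohort size).
    """
    tissue_locs: dict[Location, float] = {
        Location.rectum: 0.118,
        Location.sigmoid_colon: 0.225,
        Location.rectosigmoid_junction: 0.118,
        Location.transverse_colon: 0.064,
        Location.descending_colon: 0.036,
        Location.ascending_colon: 0.141,
        Location.colon_NOS: 0.100,
        Location.rectum_NOS: 0.080,
        Location.hepatic_flexure: 0.025,
        Location.splenic_flexure: 0.025,
        Location.other: 0.010,
        Location.unknown: 0.058,
    }
    anchor_tissue_prob: dict[Location, float] = {
        Location.rectum: 0.870,
        Location.sigmoid_colon: 0.761,
        Location.rectosigmoid_junction: 0.761,
        Location.transverse_colon: 0.880,
        Location.descending_colon: 0.857,
        Location.ascending_colon: 0.945,
        "default": 0.950,  # type: ignore[dict-item]
    }
    beta_cfg = BetaSimConfig(
        n_case=391,
        n_control=45,
        n_adenoma=0,
        genes=[
            GeneBetaSpec(
                gene="SDC2",
                meth_frac={Group.CRC: anchor_tissue_prob, Group.adenoma: 0.6,
                           Group.normal: 0.02},
                meth_mean=0.492, meth_sd=0.178,
                unmeth_mean=0.067, unmeth_sd=0.018,
            ),
            GeneBetaSpec(
                gene="TFPI2",
                meth_frac={Group.CRC: 0.95, Group.adenoma: 0.6, Group.normal: 0.02},
                meth_mean=0.558, meth_sd=0.149,
                unmeth_mean=0.161, unmeth_sd=0.078,
            ),
        ],
        location_distribution=tissue_locs,
        complement_given_anchor_neg={Group.CRC: 0.88, Group.adenoma: 0.5,
                                     Group.normal: 0.02},
        probes_per_island=12,
        seed=0,
    )

    crc_sites = STOOL_SUBSITE_SENSITIVITY[Group.CRC]
    ade_sites = STOOL_SUBSITE_SENSITIVITY[Group.adenoma]
    n_crc = sum(n for n, _, _ in crc_sites.values())
    n_ade = sum(n for n, _, _ in ade_sites.values())
    ct_cfg = CtSimConfig(
        n_per_group={Group.CRC: 289, Group.adenoma: 190, Group.normal: 217},
        actb_ct={Group.CRC: (26.0, 1.5), Group.adenoma: (27.5, 1.5),
                 Group.normal: (29.0, 1.5)},
        location_distribution={
            Group.CRC: {loc: n / n_crc for loc, (n, _, _) in crc_sites.items()},
            Group.adenoma: {loc: n / n_ade for loc, (n, _, _) in ade_sites.items()},
            Group.normal: {Location.unknown: 1.0},
        },
        anchor_meth_prob={
            Group.CRC: {loc: sd for loc, (_, sd, _) in crc_sites.items()},
            Group.adenoma: {loc: sd for loc, (_, sd, _) in ade_sites.items()},
            Group.normal: 0.01,
        },
        complement_meth_prob={Group.CRC: 0.938, Group.adenoma: 0.95,
                              Group.normal: 0.5},
        complement_given_anchor_neg={
            Group.CRC: _rate_map(Group.CRC),
            Group.adenoma: _rate_map(Group.adenoma),
            Group.normal: 0.0289,
        },
        seed=0,
    )
    return beta_cfg, ct_cfg


def planted_screen_config(
    n_decoys: int = 50,
    n_case: int = 400,
    n_control: int = 45,
    probes_per_island: int = 12,
    seed: int = 0,
) -> BetaSimConfig:
    """β cohort with one planted complement gene among low-rate decoys.

    Decoy islands have complement probability ≤ 0.1 (evenly spread over
    0.02–0.10) independent of the anchor; the planted complement keeps the
    0.88 dependence.  Used for parameter-recovery checks: the screen should
    rank the planted gene first.
    """
    base, _ = default_paper_like_config()
    genes = [g for g in base.genes]
    for i in range(n_decoys):
        frac = 0.02 + 0.08 * (i / max(n_decoys - 1, 1))
        genes.append(
            GeneBetaSpec(
                gene=f"DEC{i + 1:03d}",
                meth_frac={Group.CRC: frac, Group.adenoma: frac, Group.normal: 0.02},
                meth_mean=0.558, meth_sd=0.149,
                unmeth_mean=0.161, unmeth_sd=0.078,
            )
        )
    return replace(
        base,
        n_case=n_case,
        n_control=n_control,
        genes=genes,
        probes_per_island=probes_per_island,
        seed=seed,
    )
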