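"""Synthetic stand-ins for the study's two kinds of raw data.

Two independent generators:

* a differential-expression table generator over a ~5,000-gene
  transcriptome with a configurable number of background-misregulated
  genes (~1,300 by default) and optional *planted* pathways whose member
  genes are pushed coherently up or down — ground truth for power and
  type-I calibration of the pathway directionality test;

* a batch-fermentation simulator (Monod growth on glucose, a fermentative/
  respiratory flux split, diauxic shift to ethanol, off-gas profile, and
  an optional co-cultured bacterial population killed by ethanol) — ground
  truth for every kinetics operation.

The fermentation model tracks carbon explicitly: CO2 is whatever glucose
carbon is not fixed in biomass or excreted products, split into a
fermentative share (equimolar with ethanol) and a respiratory share for
which O2 consumption is equimolar with CO2 (respiratory quotient 1).  The
culture-level RQ during glucose growth is therefore analytic:
RQ = 1 + phi / (3 (1 - phi)), where phi is the fermentative fraction of
non-assimilated glucose carbon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Pathway, PathwaySet
from .kinetics import MOLAR_VOLUME_25C as MOLAR_VOLUME_GAS

# carbon mass fractions (g C / g) of the tracked species
C_GLUCOSE = 72.06 / 180.16
C_ETHANOL = 24.02 / 46.07
C_ACETATE = 24.02 / 60.05
C_GLYCEROL = 36.03 / 92.09
C_PYRUVATE = 36.03 / 88.06
C_BIOMASS = 12.011 / 24.63      # CH1.8O0.5N0.2, 24.63 g/C-mol
MW_CARBON = 12.011

#: plate-count proxy: colony-forming units per mL per (g DW / L) of yeast
YEAST_CFU_PER_GDW = 4.6e7


# ---------------------------------------------------------------------------
# differential-expression generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """A pathway whose members are coherently pushed in one direction."""

    pathway_id: str
    effect_fraction: float      # fraction of member genes forced, in [0, 1]
    direction: int              # +1 or -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must lie in [0, 1]")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class SyntheticDEConfig:
    """Study-scale defaults: ~5,000 genes, ~1,300 misregulated, 118 pathways."""

    n_genes: int = 5000
    n_pathways: int = 118
    pathway_size_range: tuple[int, int] = (4, 30)
    planted: tuple[PlantedEffect, ...] = ()
    background_misregulated: int = 1300
    #: |FC| of a misregulated gene is 1.5 * exp(|N(0, sigma)|) (half-log-normal
    #: above the calling threshold)
    fc_sigma: float = 0.5
    #: sd of the log-ratio of unchanged genes (kept below the 1.5 threshold)
    null_sigma: float = 0.15
    n_replicates: int = 3
    #: replicate-to-replicate multiplicative log-normal noise on the ratio
    replicate_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid pathway size range")
        if self.background_misregulated > self.n_genes:
            raise ValueError("more misregulated genes than genes")


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_pathways(config: SyntheticDEConfig,
                      categories: Sequence[str] = ("metabolism",),
                      ) -> PathwaySet:
    """Random gene sets emulating a curated pathway collection.

    Sizes are uniform over ``pathway_size_range``; whenever at least two
    pathways are requested, one set of size 10 and one of size 21 are
    guaranteed (the sizes of glycolysis and the TCA cycle, the collection's
    scientifically salient members).  Genes are drawn without replacement
    within a pathway; pathways may overlap.  Categories are assigned
    round-robin from ``categories``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.pathway_size_range
    if hi > config.n_genes:
        raise ValueError("pathway size exceeds the gene universe")
    genes = np.array(_gene_ids(config.n_genes))
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    if config.n_pathways >= 2:
        if 10 not in sizes and lo <= 10 <= hi:
            sizes[0] = 10
        if 21 not in sizes and lo <= 21 <= hi:
            sizes[1] = 21
    pathways = []
    for i, n in enumerate(sizes):
        members = rng.choice(genes, size=int(n), replace=False)
        pathways.append(Pathway(
            pathway_id=f"PW{i + 1:04d}",
            genes=frozenset(members.tolist()),
            category=categories[i % len(categories)],
        ))
    return PathwaySet(pathways)


def _planted_gene_count(effect_fraction: float, size: int) -> int:
    # round-half-up
    return int(math.floor(effect_fraction * size + 0.5))


def generate_de_table(config: SyntheticDEConfig,
                      pathways: PathwaySet | None = None,
                      condition: str = "aerobic") -> list[pd.DataFrame]:
    """Triplicate DE tables with planted directional pathway signals.

    Unchanged genes get a signed fold change near +/-1 (|FC| < 1.5) and a
    uniform p-value.  Background-misregulated genes get |FC| >= 1.5 with a
    random sign and a strongly significant p-value (log10 p uniform on
    [-8, -3.5]), so essentially all survive FDR correction.  For each
    planted pathway, round(f * n) member genes are forced to the planted
    direction.  Replicates share the per-gene direction and p-value (the
    replicate-combined test) and differ by multiplicative log-normal noise
    on the expression ratio.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_genes
    genes = _gene_ids(n)
    index = {g: i for i, g in enumerate(genes)}

    sign = np.zeros(n, dtype=np.int8)
    planted_idx: list[int] = []
    if config.planted:
        if pathways is None:
            raise ValueError("planted effects need the pathway collection")
        for effect in config.planted:
            members = sorted(pathways[effect.pathway_id].genes)
            k = _planted_gene_count(effect.effect_fraction, len(members))
            chosen = rng.choice(len(members), size=k, replace=False)
            for j in chosen:
                gi = index[members[j]]
                sign[gi] = effect.direction
                planted_idx.append(gi)
    free = np.setdiff1d(np.arange(n), np.array(planted_idx, dtype=int))
    n_bg = min(config.background_misregulated, len(free))
    bg = rng.choice(free, size=n_bg, replace=False)
    sign[bg] = rng.choice([-1, 1], size=n_bg)

    misreg = sign != 0
    log_ratio = np.empty(n)
    # unchanged genes: small log-ratio, capped strictly below the threshold
    z = rng.normal(0.0, config.null_sigma, size=n)
    cap = math.log(1.5) * 0.98
    log_ratio[:] = np.clip(z, -cap, cap)
    # misregulated genes: |FC| = 1.5 * exp(|N(0, sigma)|), signed
    bump = np.abs(rng.normal(0.0, config.fc_sigma, size=int(misreg.sum())))
    log_ratio[misreg] = sign[misreg] * (math.log(1.5) + bump)

    p = rng.uniform(0.0, 1.0, size=n)
    p[misreg] = 10.0 ** rng.uniform(-8.0, -3.5, size=int(misreg.sum()))

    tables = []
    for r in range(1, config.n_replicates + 1):
        noise = rng.normal(0.0, config.replicate_sigma, size=n)
        ratio = np.exp(log_ratio + noise)
        fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
        df = pd.DataFrame({
            "gene_id": genes,
            "fold_change": fc,
            "p_value": p,
            "replicate_id": f"rep{r}",
        })
        df.attrs["condition"] = condition
        tables.append(df)
    return tables


# ---------------------------------------------------------------------------
# batch-fermentation / co-culture simulator
# ---------------------------------------------------------------------------

@dataclass
class FermentationParams:
    """Parameters of the aerobic batch model; defaults emulate a
    Crabtree-positive regime on 20 g/L glucose."""

    mu_glc: float = 0.25            # max specific growth rate on glucose, 1/h
    mu_eth: float = 0.12            # max specific growth rate on ethanol, 1/h
    y_xs: float = 0.12              # biomass yield on glucose, g/g
    y_xe: float = 0.60              # biomass yield on ethanol, g/g
    y_acetate: float = 0.02         # acetate yield on glucose, g/g
    y_glycerol: float = 0.01
    y_pyruvate: float = 0.005
    k_s: float = 0.10               # Monod constant for glucose, g/L
    k_e: float = 0.10               # Monod constant for ethanol, g/L
    diauxic_lag: float = 3.0        # h between glucose exhaustion and
                                    # ethanol utilization
    fermentative_fraction: float = 0.75   # phi: share of non-assimilated
                                          # glucose carbon routed to ethanol
    glucose_0: float = 20.0         # g/L
    yeast_log10_cfu_0: float = 5.0  # log10 cfu/mL at inoculation
    bacteria_log10_cfu_0: float = 4.0
    bacteria_mu: float = 0.10       # 1/h, on glucose (slowed by competition)
    bacteria_death_rate: float = 0.3  # 1/h per (g/L ethanol above threshold)
    ethanol_kill_threshold: float = 0.2  # g/L
    gas_flow: float = 60.0          # L/h
    volume: float = 1.0             # L
    y_o2_in: float = 0.2095         # air
    y_co2_in: float = 0.0004
    dt: float = 0.05                # integration step, h
    horizon: float = 60.0           # h
    sample_interval: float = 0.25   # output sampling, h
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fermentative_fraction <= 1.0:
            raise ValueError("fermentative_fraction must lie in [0, 1]")
        for name in ("mu_glc", "mu_eth", "y_xs", "y_xe", "k_s", "k_e",
                     "dt", "horizon", "gas_flow", "volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.residual_carbon_per_g_glucose() < 0:
            raise ValueError(
                "yields fix more carbon than glucose supplies; lower y_xs "
                "or the product yields")

    def residual_carbon_per_g_glucose(self) -> float:
        """g of glucose carbon per g glucose left after biomass and
        excreted side products — the pool split between fermentation and
        respiration."""
        return (C_GLUCOSE - self.y_xs * C_BIOMASS - self.y_acetate * C_ACETATE
                - self.y_glycerol * C_GLYCEROL - self.y_pyruvate * C_PYRUVATE)

    def ethanol_yield(self) -> float:
        """Analytic ethanol yield on glucose (g/g) implied by phi.

        Of the fermented carbon, two thirds end in ethanol and one third in
        CO2 (glucose C6 -> 2 ethanol C2 + 2 CO2).
        """
        return (2.0 / 3.0) * self.fermentative_fraction \
            * self.residual_carbon_per_g_glucose() / C_ETHANOL

    def analytic_rq(self) -> float:
        """Culture RQ during glucose growth: 1 + phi / (3 (1 - phi))."""
        phi = self.fermentative_fraction
        if phi >= 1.0:
            return math.inf
        return 1.0 + phi / (3.0 * (1.0 - phi))

    @classmethod
    def with_ethanol_yield(cls, y_ethanol: float, **kwargs) -> "FermentationParams":
        """Build params with phi solved from a target ethanol yield (g/g)."""
        probe = cls(fermentative_fraction=0.0, **kwargs)
        c_rem = probe.residual_carbon_per_g_glucose()
        phi = y_ethanol * C_ETHANOL / ((2.0 / 3.0) * c_rem)
        if not 0.0 <= phi <= 1.0:
            raise ValueError(
                f"ethanol yield {y_ethanol} g/g is infeasible with these "
                f"yields (implied fermentative fraction {phi:.3f})")
        return replace(probe, fermentative_fraction=phi)

    @classmethod
    def with_rq(cls, rq: float, **kwargs) -> "FermentationParams":
        """Build params with phi solved from a target glucose-phase RQ."""
        if rq < 1.0:
            raise ValueError("the model cannot produce RQ < 1 on glucose")
        phi = 3.0 * (rq - 1.0) / (1.0 + 3.0 * (rq - 1.0))
        return cls(fermentative_fraction=phi, **kwargs)


@dataclass
class SimulationResult:
    timecourse: pd.DataFrame
    gas_profile: pd.DataFrame
    params: FermentationParams
    t_glucose_exhausted: float | None = None


def simulate_batch_fermentation(params: FermentationParams,
                                co_culture: bool = False) -> SimulationResult:
    """Integrate the batch model with fixed-step explicit Euler.

    Glucose phase: Monod growth; the glucose carbon not assimilated or
    excreted as acetate/glycerol/pyruvate is split ``phi`` to fermentation
    (ethanol + equimolar CO2, no O2) and ``1 - phi`` to respiration (CO2
    with equimolar O2).  After glucose exhaustion and the diauxic lag, the
    culture grows aerobically on ethanol, then on acetate.  In co-culture
    mode a bacterial population grows on glucose and dies at
    ``bacteria_death_rate * max(0, ethanol - threshold)``; its substrate
    consumption is negligible at plate-count scales and is not fed back.

    Consumption fluxes are rate-limited so no state goes negative; cumulative
    CO2 and O2 (mmol/L) are carried in the time course so carbon balances
    close to integration accuracy.
    """
    p = params
    if p.dt > 0.2:
        raise ValueError(
            f"integration step dt={p.dt} h is too coarse for these dynamics; "
            "use dt <= 0.2 h")
    n_steps = int(round(p.horizon / p.dt))
    every = max(1, int(round(p.sample_interval / p.dt)))

    X = 10.0 ** p.yeast_log10_cfu_0 / YEAST_CFU_PER_GDW   # g DW / L
    S = p.glucose_0
    E = A = G = P_ = 0.0
    Nb = 10.0 ** p.bacteria_log10_cfu_0 if co_culture else 0.0
    co2_cum = o2_cum = 0.0       # mmol/L
    t_glc_done: float | None = None

    tc_rows, gas_rows = [], []

    def record(t: float, co2_rate: float, o2_rate: float) -> None:
        tc_rows.append((t, X, X * 2.0, S, E, A, G, P_,
                        math.log10(max(X * YEAST_CFU_PER_GDW, 1.0)),
                        math.log10(max(Nb, 1.0)) if co_culture else np.nan,
                        co2_cum, o2_cum))
        n_in = p.gas_flow / MOLAR_VOLUME_GAS          # mol/h
        our = o2_rate / 1000.0 * p.volume             # mol/h transferred
        ctr = co2_rate / 1000.0 * p.volume
        n_out = n_in - our + ctr
        gas_rows.append((t, p.y_o2_in,
                         (n_in * p.y_o2_in - our) / n_out,
                         p.y_co2_in,
                         (n_in * p.y_co2_in + ctr) / n_out,
                         p.gas_flow, p.volume))

    phi = p.fermentative_fraction
    c_rem_per_g = p.residual_carbon_per_g_glucose()

    for step in range(n_steps + 1):
        t = step * p.dt
        co2_rate = o2_rate = 0.0   # mmol/L/h

        # --- glucose phase -------------------------------------------------
        if S > 0:
            mu = p.mu_glc * S / (p.k_s + S)
            r_s = mu * X / p.y_xs                     # g glucose /L/h
            scale = min(1.0, S / (r_s * p.dt)) if r_s > 0 else 0.0
            r_s *= scale
            mu_eff = mu * scale
            r_x = mu_eff * X
            r_a = p.y_acetate * r_s
            r_g = p.y_glycerol * r_s
            r_p = p.y_pyruvate * r_s
            c_rem = c_rem_per_g * r_s                 # g C /L/h
            r_e = (2.0 / 3.0) * phi * c_rem / C_ETHANOL
            co2_ferm = (1.0 / 3.0) * phi * c_rem / MW_CARBON * 1000.0
            co2_resp = (1.0 - phi) * c_rem / MW_CARBON * 1000.0
            co2_rate += co2_ferm + co2_resp
            o2_rate += co2_resp                       # RQ = 1 for that share
            X += r_x * p.dt
            S = max(0.0, S - r_s * p.dt)
            E += r_e * p.dt
            A += r_a * p.dt
            G += r_g * p.dt
            P_ += r_p * p.dt
            if S <= 0 and t_glc_done is None:
                t_glc_done = t + p.dt
        elif t_glc_done is None:
            t_glc_done = t

        # --- post-diauxic phase -------------------------------------------
        if t_glc_done is not None and t >= t_glc_done + p.diauxic_lag:
            if E > 0:
                mu_e = p.mu_eth * E / (p.k_e + E)
                r_econs = mu_e * X / p.y_xe
                scale = min(1.0, E / (r_econs * p.dt)) if r_econs > 0 else 0.0
                r_econs *= scale
                r_x = p.y_xe * r_econs
                c_e = r_econs * C_ETHANOL / MW_CARBON      # C-mol /L/h
                c_x = r_x * C_BIOMASS / MW_CARBON
                co2 = max(0.0, c_e - c_x) * 1000.0
                o2 = max(0.0, (6.0 * c_e - 4.2 * c_x) / 4.0) * 1000.0
                co2_rate += co2
                o2_rate += o2
                X += r_x * p.dt
                E = max(0.0, E - r_econs * p.dt)
            elif A > 0:
                # acetate mop-up, electron-balanced (gamma = 4 -> RQ ~ 1)
                r_acons = 0.10 * X * A / (0.05 + A)
                scale = min(1.0, A / (r_acons * p.dt)) if r_acons > 0 else 0.0
                r_acons *= scale
                r_x = 0.4 * r_acons
                c_a = r_acons * C_ACETATE / MW_CARBON
                c_x = r_x * C_BIOMASS / MW_CARBON
                co2_rate += max(0.0, c_a - c_x) * 1000.0
                o2_rate += max(0.0, (4.0 * c_a - 4.2 * c_x) / 4.0) * 1000.0
                X += r_x * p.dt
                A = max(0.0, A - r_acons * p.dt)

        # --- bacteria ------------------------------------------------------
        if co_culture and Nb > 0:
            mu_b = p.bacteria_mu * S / (p.k_s + S)
            death = p.bacteria_death_rate * max(0.0, E - p.ethanol_kill_threshold)
            Nb *= math.exp((mu_b - death) * p.dt)
            if Nb < 1.0:
                Nb = 0.0

        co2_cum += co2_rate * p.dt
        o2_cum += o2_rate * p.dt
        if step % every == 0:
            record(t, co2_rate, o2_rate)

    tc = pd.DataFrame(tc_rows, columns=[
        "time", "biomass_dw", "od600", "glucose", "ethanol", "acetate",
        "glycerol", "pyruvate", "yeast_cfu", "bacteria_cfu",
        "co2_cum_mmol", "o2_cum_mmol"])
    if not co_culture:
        tc = tc.drop(columns=["bacteria_cfu"])
    gp = pd.DataFrame(gas_rows, columns=[
        "time", "y_o2_in", "y_o2_out", "y_co2_in", "y_co2_out",
        "gas_flow", "volume"])
    return SimulationResult(tc, gp, p, t_glc_done)


def carbon_balance(result: SimulationResult) -> dict[str, float]:
    """Carbon accounting of a simulation from its own outputs.

    Returns consumed glucose carbon, carbon recovered in biomass + products
    + cumulative CO2, and the relative imbalance (should be ~0).
    """
    tc = result.timecourse
    first, last = tc.iloc[0], tc.iloc[-1]
    consumed = (first["glucose"] - last["glucose"]) * C_GLUCOSE
    recovered = (
        (last["biomass_dw"] - first["biomass_dw"]) * C_BIOMASS
        + (last["ethanol"] - first["ethanol"]) * C_ETHANOL
        + (last["acetate"] - first["acetate"]) * C_ACETATE
        + (last["glycerol"] - first["glycerol"]) * C_GLYCEROL
        + (last["pyruvate"] - first["pyruvate"]) * C_PYRUVATE
        + (last["co2_cum_mmol"] - first["co2_cum_mmol"]) / 1000.0 * MW_CARBON
    )
    rel = (recovered - consumed) / consumed if consumed > 0 else float("nan")
    return {"consumed_gC": float(consumed), "recovered_gC": float(recovered),
            "relative_imbalance": float(rel)}
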