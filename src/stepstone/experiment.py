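"""End-to-end seeded experiments at desk scale.

Drives the full pipeline — endpoint secondary structures, pathway
enumeration, stepping-stone synthesis, island design, joint-ensemble rate
estimation, rate-surface fitting, and the Markov master-equation analysis
— at problem sizes that run on one CPU in minutes.  Every stage is
deterministic given the experiment seed.  Also provides the tiny
deterministic fixtures the test suite builds its oracles on.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignConfig, Island, run_design
from .energy import InteractionMatrix, default_matrix
from .markov import (
    build_rate_matrix,
    global_balance_residual,
    propagate,
    stationary_distribution,
)
from .ratefit import (
    RateObservation,
    RateSurfaceParams,
    equilibrium_probabilities,
    fit_rate_surface,
    log_rate,
    plane_fit_log_ratio,
)
from .rates import (
    RateConfig,
    estimate_rate_constants,
    estimate_rates_direct,
    sample_joint,
)
from .sspath import SS_1PGB, SS_2GYC, build_path, enumerate_pathways
from .structgen import Structure, common_contacts, synth_structure

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "sample_stepping_stones",
    "measure_pair_rates",
    "rate_ratio_study",
    "observations_from_params",
    "make_fixtures",
]


@dataclass
class ExperimentConfig:
    """Desk-scale pipeline configuration.

    ``pair_window`` limits rate measurements to structure pairs within
    that many positions of each other along the stepping-stone ordering,
    keeping the committor well-sampled in both directions.
    """

    src_ss: str = SS_1PGB
    dst_ss: str = SS_2GYC
    n_stepping_stones: int = 12
    extra_contact_range: tuple[int, int] = (12, 24)
    pair_window: int = 3
    mapping_index: int = 0
    design: DesignConfig = field(default_factory=lambda: DesignConfig(n_sweeps=100))
    rate: RateConfig = field(
        default_factory=lambda: RateConfig(t=2.0, e_r=2.0, n_samples=100_000, burn_in=10_000)
    )
    rate_method: str = "direct"
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self):
        # accept plain dicts for the sub-configs (JSON config files)
        if isinstance(self.design, dict):
            self.design = DesignConfig(**self.design)
        if isinstance(self.rate, dict):
            self.rate = RateConfig(**self.rate)
        self.extra_contact_range = tuple(self.extra_contact_range)
        if self.n_stepping_stones < 2:
            raise ValueError("need at least two stepping stones")
        lo, hi = self.extra_contact_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid extra_contact_range")


def sample_stepping_stones(cfg: ExperimentConfig) -> list[Structure]:
    """Stepping stones sampled evenly along one realized pathway.

    Each sampled secondary-structure string is realized as a synthetic
    contact map whose extra long-range contact count is drawn from
    ``extra_contact_range`` (seeded), so both hydrogen-bond counts and
    compactness vary across the set.
    """
    rng = np.random.default_rng(cfg.seed)
    mappings = enumerate_pathways(cfg.src_ss, cfg.dst_ss)
    mapping = mappings[cfg.mapping_index % len(mappings)]
    path = build_path(cfg.src_ss, cfg.dst_ss, mapping, rng_seed=cfg.seed)
    idx = np.linspace(0, len(path.states) - 1, cfg.n_stepping_stones).round().astype(int)
    lo, hi = cfg.extra_contact_range
    structures = []
    for rank, i in enumerate(idx):
        ss = path.states[i]
        base = synth_structure(ss, None, rng_seed=0).n_contacts
        extra = int(rng.integers(lo, hi + 1))
        structures.append(
            synth_structure(
                ss,
                base + extra,
                rng_seed=int(rng.integers(2**31 - 1)),
                id=f"stone-{rank:02d}",
            )
        )
    return structures


def measure_pair_rates(
    structures: list[Structure],
    m: InteractionMatrix,
    rate_cfg: RateConfig,
    pair_window: int | None = None,
    seed: int = 0,
    method: str = "direct",
) -> list[tuple[str, str, RateObservation, object]]:
    """Monte Carlo rate estimates for structure pairs.

    ``method='direct'`` samples each island's own ensemble and reads the
    committor fraction off directly — the estimator of choice at desk
    scale, where committed fractions are large enough to observe.
    ``method='joint'`` uses the biased two-structure ensemble with
    log-space reweighting, the rare-event machinery needed when they are
    not.  Returns (id_A, id_B, observation, estimate) records; descriptor
    differences are B minus A.
    """
    if method not in ("direct", "joint"):
        raise ValueError("method must be 'direct' or 'joint'")
    records = []
    n = len(structures)
    for i, j in itertools.combinations(range(n), 2):
        if pair_window is not None and j - i > pair_window:
            continue
        a, b = structures[i], structures[j]
        cfg = RateConfig(
            t=rate_cfg.t,
            e_r=rate_cfg.e_r,
            mu=rate_cfg.mu,
            n_samples=rate_cfg.n_samples,
            burn_in=rate_cfg.burn_in,
            rng_seed=seed + 7919 * i + j,
            alphabet=rate_cfg.alphabet,
        )
        if method == "direct":
            est = estimate_rates_direct(a, b, m, cfg)
        else:
            est = estimate_rate_constants(sample_joint(a, b, m, cfg), cfg)
        obs = RateObservation(
            de_hb=b.hb_energy - a.hb_energy,
            dn_c=b.n_contacts - a.n_contacts,
            q=common_contacts(a, b).q_frac,
            k_ab=est.k_ab,
            k_ba=est.k_ba,
            se_ab=est.se_ab,
            se_ba=est.se_ba,
        )
        records.append((a.id, b.id, obs, est))
    return records


def rate_ratio_study(records, structures, params: RateSurfaceParams) -> pd.DataFrame:
    """Total-rate ratio R_AB/R_BA = (k_AB/k_BA) (P_A/P_B) per pair, with
    equilibrium probabilities from the fitted descriptor model; detailed
    balance predicts a distribution concentrated at 1."""
    ids = [s.id for s in structures]
    probs = equilibrium_probabilities(structures, params)
    p = dict(zip(ids, probs))
    rows = []
    for id_a, id_b, obs, _ in records:
        if obs.k_ab <= 0 or obs.k_ba <= 0:
            continue
        ratio = (obs.k_ab / obs.k_ba) * (p[id_a] / p[id_b])
        rows.append(
            {
                "structure_a": id_a,
                "structure_b": id_b,
                "k_ab": obs.k_ab,
                "k_ba": obs.k_ba,
                "p_a": p[id_a],
                "p_b": p[id_b],
                "r_ratio": ratio,
            }
        )
    return pd.DataFrame(rows)


def observations_from_params(
    params: RateSurfaceParams,
    n: int = 60,
    rng_seed: int = 0,
    noise: float = 0.0,
    de_hb_scale: float = 4.0,
    dn_c_scale: float = 12.0,
) -> list[RateObservation]:
    """Synthetic rate observations drawn exactly from the analytic family,
    optionally with multiplicative log-normal noise — the generating
    process for fit-recovery tests."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n):
        de = float(rng.normal(0.0, de_hb_scale))
        dn = float(rng.normal(0.0, dn_c_scale))
        q = float(rng.uniform(0.2, 1.0))
        k_ab = float(np.exp(log_rate(params, de, dn, q)))
        k_ba = float(np.exp(log_rate(params, -de, -dn, q)))
        if noise > 0:
            k_ab *= float(np.exp(rng.normal(0.0, noise)))
            k_ba *= float(np.exp(rng.normal(0.0, noise)))
        out.append(RateObservation(de_hb=de, dn_c=dn, q=q, k_ab=k_ab, k_ba=k_ba))
    return out


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Full pipeline; returns a report dict and (optionally) writes the
    stage outputs under ``cfg.outdir``."""
    m = default_matrix()
    stage = "pathways"
    try:
        mappings = enumerate_pathways(cfg.src_ss, cfg.dst_ss)

        stage = "stepping-stones"
        structures = sample_stepping_stones(cfg)

        stage = "design"
        islands: list[Island] = []
        for k, s in enumerate(structures):
            dcfg = DesignConfig(
                t_design=cfg.design.t_design,
                e_r=cfg.design.e_r,
                n_sweeps=cfg.design.n_sweeps,
                ladder=list(cfg.design.ladder),
                exchange_interval=cfg.design.exchange_interval,
                rng_seed=cfg.seed + 104729 + k,
                burn_in_fraction=cfg.design.burn_in_fraction,
                alphabet=cfg.design.alphabet,
            )
            islands.append(run_design(s, m, dcfg))

        stage = "rates"
        records = measure_pair_rates(
            structures, m, cfg.rate, cfg.pair_window, seed=cfg.seed, method=cfg.rate_method
        )
        observations = [obs for _, _, obs, _ in records]

        stage = "fit"
        params, diagnostics = fit_rate_surface(observations)
        plane = plane_fit_log_ratio(observations)

        stage = "equilibrium"
        ratio_table = rate_ratio_study(records, structures, params)
        probs = equilibrium_probabilities(structures, params)

        stage = "markov"
        net = build_rate_matrix(structures, params)
        pi = stationary_distribution(net)
        times = np.geomspace(1e-2, 1e4, 13)
        p0 = np.zeros(net.n_states)
        p0[0] = 1.0
        traj = propagate(net, p0, times)
        residual, violation = global_balance_residual(net)
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc

    rate_rows = []
    for id_a, id_b, obs, est in records:
        rate_rows.append(
            {
                "structure_a": id_a,
                "structure_b": id_b,
                "k_ab": obs.k_ab,
                "k_ba": obs.k_ba,
                "se_ab": obs.se_ab,
                "se_ba": obs.se_ba,
                "de_hb": obs.de_hb,
                "dn_c": obs.dn_c,
                "q": obs.q,
                "n_eff_a": est.n_effective_a,
                "n_eff_b": est.n_effective_b,
            }
        )
    report = {
        "n_pathways": len(mappings),
        "structures": structures,
        "islands": islands,
        "rates": pd.DataFrame(rate_rows),
        "params": params,
        "fit_diagnostics": diagnostics,
        "plane_fit": plane,
        "ratio_table": ratio_table,
        "equilibrium": dict(zip([s.id for s in structures], probs)),
        "network": net,
        "stationary": pi,
        "trajectory": pd.DataFrame(traj, index=times, columns=net.ids),
        "balance_residual_max": float(np.max(np.abs(residual))),
        "detailed_balance_violation": violation,
    }

    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "structures.json").write_text(
            json.dumps([json.loads(s.to_json()) for s in structures], indent=1)
        )
        from .io import write_island_fasta

        for island in islands:
            write_island_fasta(island, out / f"island-{island.structure_id}.fasta")
        report["rates"].to_csv(out / "rates.tsv", sep="\t", index=False)
        (out / "params.json").write_text(json.dumps(params.to_dict(), indent=1))
        ratio_table.to_csv(out / "rate_ratios.tsv", sep="\t", index=False)
        report["trajectory"].to_csv(out / "trajectory.tsv", sep="\t")
    return report


def make_fixtures(seed: int = 0) -> dict:
    """Tiny deterministic fixtures for oracle-based tests (< 1 s each).

    - ``dominated``: a pair where B's energy beats A's for every sequence,
      so k_AB = 1 and k_BA = 0 exactly.
    - ``symmetric``: two structures with mirror-image descriptors, so the
      two rates agree within sampling error.
    - ``network``: six synthetic stepping stones plus known rate-family
      parameters, whose stationary distribution has the closed form
      P_X proportional to exp(-alpha_HB E_HB + alpha_c N_c).
    """
    rng = np.random.default_rng(seed)
    length = 8
    empty = frozenset()
    dominated = {
        "a": Structure(id="dom-a", length=length, ss="C" * length, contacts=empty, n_hbonds=0),
        "b": Structure(id="dom-b", length=length, ss="C" * length, contacts=empty, n_hbonds=5),
    }

    base = [(0, 3), (1, 4), (2, 5), (3, 6)]
    extra_a = [(0, 4), (1, 5)]
    extra_b = [(2, 6), (3, 7)]
    symmetric = {
        "a": Structure(
            id="sym-a", length=length, ss="C" * length,
            contacts=frozenset(base + extra_a), n_hbonds=3,
        ),
        "b": Structure(
            id="sym-b", length=length, ss="C" * length,
            contacts=frozenset(base + extra_b), n_hbonds=3,
        ),
    }

    ss = "CC" + "E" * 3 + "C" + "H" * 6 + "C" * 4 + "H" * 5 + "C" + "E" * 3 + "CCC"
    net_structs = []
    floor = synth_structure(ss, None, rng_seed=0).n_contacts
    for k in range(6):
        net_structs.append(
            synth_structure(
                ss,
                floor + 4 * k,
                rng_seed=int(rng.integers(2**31 - 1)),
                id=f"net-{k}",
            )
        )
    net_params = RateSurfaceParams(
        log_k_max=0.0, alpha_hb=0.6, alpha_c=0.15, alpha_q=2.0, q_mid=0.5
    )
    return {
        "dominated": dominated,
        "symmetric": symmetric,
        "network": {"structures": net_structs, "params": net_params},
    }
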