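"""Seeded generators for synthetic connectomes, couplings, activity and
two-group cohorts.

Real cohort data for this kind of study (regional BOLD series plus
tractography-derived structural connectomes) are rarely shareable, so the
generators here emulate the full data-generating process end to end:

1. a sparse symmetric nonnegative structural connectome ``W`` with
   heavy-tailed weights, connected by construction;
2. a signed ground-truth coupling matrix with ``|J|`` proportional to
   ``W`` and per-edge excitatory/inhibitory signs;
3. binary +/-1 activity sampled from the Boltzmann distribution of that
   coupling matrix at a chosen inverse temperature (thinned Metropolis
   chains, so samples are approximately independent — matching the
   exchangeability assumption of the pseudolikelihood; a ``trace`` mode
   yields autocorrelated consecutive sweeps instead);
4. continuous noisy observations of the binary states, to exercise the
   z-score/binarize front end;
5. two matched subject cohorts whose excitation/inhibition balance differs
   by a controllable shift, mirroring a carrier/noncarrier design.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from .connectome_io import ActivityTimeSeries, BinarizedActivity, StructuralConnectome
from .ising_sim import _run_chain
from .pmem_inference import CouplingMatrix, _coerce_J, _coerce_W

__all__ = [
    "SyntheticSpec",
    "CohortSubject",
    "gen_structural",
    "gen_ground_truth_coupling",
    "gen_activity",
    "gen_continuous",
    "gen_cohort",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generators.

    Defaults mirror the target application: ``N = 80`` regions observed for
    ``t_max = 236`` time points (an 8-minute scan at TR = 2 s), a
    structural edge density of 0.3 (typical of tractography-derived
    connectomes at this parcellation), balanced excitation
    (``excitatory_fraction = 0.5``), unit coupling scale (``|J| = W``,
    matching the constraint's unit-normalization convention) at inverse
    temperature 0.8 (a paramagnetic but correlated regime), and
    observation noise of 0.5 SD on the +/-1 states.

    ``group_shift`` injects a relative excitation/inhibition shift into
    group B of a cohort: the per-region E/I ratio of group B is scaled by
    ``1 / (1 - group_shift)``, so the expected region-wise
    ``delta = 1 - ratio_A / ratio_B`` of the cohort equals ``group_shift``.
    ``roi_sd`` gives regions a shared baseline excitability profile;
    ``w_jitter_sd`` is the per-subject lognormal jitter on ``W`` standing
    in for inter-individual anatomical variability.
    """

    N: int = 80
    t_max: int = 236
    density: float = 0.3
    excitatory_fraction: float = 0.5
    coupling_scale: float = 1.0
    beta_true: float = 0.8
    noise_sd: float = 0.5
    group_shift: float = 0.0
    roi_sd: float = 0.05
    w_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if not (0 <= self.excitatory_fraction <= 1):
            raise ValueError("excitatory_fraction must be in [0, 1]")
        shifted = _shift_fraction(self.excitatory_fraction, self.group_shift)
        if not (0 <= shifted <= 1):
            raise ValueError("group_shift pushes the excitatory fraction outside [0, 1]")
        if self.coupling_scale <= 0 or self.beta_true <= 0 or self.noise_sd < 0:
            raise ValueError("coupling_scale, beta_true must be > 0; noise_sd >= 0")


def _shift_fraction(p: float, shift: float) -> float:
    """Fraction whose odds p/(1-p) are scaled by 1/(1-shift)."""
    if shift == 0 or p in (0.0, 1.0):
        return p
    odds = p / (1.0 - p) / (1.0 - shift)
    return odds / (1.0 + odds)


@dataclass
class CohortSubject:
    """One synthetic subject: anatomy, ground-truth couplings and activity."""

    subject_id: str
    structural: StructuralConnectome
    coupling_true: CouplingMatrix
    states: Optional[BinarizedActivity] = None
    activity: Optional[ActivityTimeSeries] = None


def gen_structural(spec: SyntheticSpec, seed: int | None = None) -> StructuralConnectome:
    """Random structural connectome at the requested edge density.

    Edges are Bernoulli(density) on distinct pairs with lognormal
    (heavy-tailed) weights, the graph is made connected by bridging
    components, and weights are normalized to a maximum of 1.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    N = spec.N
    iu = np.triu_indices(N, k=1)
    mask = rng.random(iu[0].size) < spec.density
    W = np.zeros((N, N))
    W[iu[0][mask], iu[1][mask]] = rng.lognormal(mean=0.0, sigma=1.0, size=int(mask.sum()))
    W = W + W.T
    # bridge disconnected components so Monte Carlo dynamics are irreducible
    n_comp, labels = csgraph.connected_components(csr_matrix(W > 0), directed=False)
    while n_comp > 1:
        anchor = rng.choice(np.flatnonzero(labels == 0))
        for c in range(1, n_comp):
            other = rng.choice(np.flatnonzero(labels == c))
            w = rng.lognormal(mean=0.0, sigma=1.0)
            W[anchor, other] = W[other, anchor] = w
        n_comp, labels = csgraph.connected_components(csr_matrix(W > 0), directed=False)
    W /= W.max()
    return StructuralConnectome(W, normalization_mode="max_one")


def gen_ground_truth_coupling(
    W: StructuralConnectome,
    spec: SyntheticSpec,
    seed: int | None = None,
    edge_sign_prob: np.ndarray | None = None,
) -> CouplingMatrix:
    """Signed couplings with ``|J| = coupling_scale * W``.

    Each structural edge gets a positive sign with probability
    ``spec.excitatory_fraction`` (or, when ``edge_sign_prob`` is given, a
    per-edge probability, e.g. from a regional excitability profile).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    Wm = _coerce_W(W)
    N = Wm.shape[0]
    iu = np.triu_indices(N, k=1)
    p = np.full(iu[0].size, spec.excitatory_fraction) if edge_sign_prob is None else edge_sign_prob
    signs = np.where(rng.random(iu[0].size) < p, 1.0, -1.0)
    J = np.zeros((N, N))
    J[iu] = signs * spec.coupling_scale * Wm[iu]
    J = J + J.T
    labels = list(W.region_labels) if isinstance(W, StructuralConnectome) else []
    return CouplingMatrix(J, labels, "ground_truth")


def gen_activity(
    J,
    beta_true: float,
    t_max: int,
    seed: int = 0,
    thin: int | None = None,
    burn_in: int | None = None,
    mode: str = "independent",
) -> BinarizedActivity:
    """Sample ``t_max`` +/-1 configurations from the Boltzmann distribution
    of ``J`` at inverse temperature ``beta_true``.

    ``mode="independent"`` (default) records every ``thin``-th sweep
    (default N sweeps apart) after a burn-in of 20 N sweeps, giving
    approximately independent samples; ``mode="trace"`` records consecutive
    sweeps, emulating an autocorrelated empirical series.
    """
    Jm = _coerce_J(J)
    N = Jm.shape[0]
    if mode == "trace":
        thin_eff = 1
    else:
        thin_eff = thin if thin is not None else N
    burn = burn_in if burn_in is not None else 20 * N
    states, _ = _run_chain(Jm, beta_true, t_max, burn, seed, "random", "metropolis", thin=thin_eff)
    labels = list(J.region_labels) if isinstance(J, CouplingMatrix) else []
    return BinarizedActivity(states, float("nan"), labels)


def gen_continuous(S: BinarizedActivity, noise_sd: float, seed: int = 0) -> ActivityTimeSeries:
    """Continuous observations: the +/-1 states plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    values = S.states.astype(float) + rng.normal(0.0, noise_sd, size=S.states.shape)
    return ActivityTimeSeries(values, list(S.region_labels))


def _roi_profile(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """Region-level baseline excitatory fractions shared across subjects."""
    return np.clip(
        spec.excitatory_fraction + rng.normal(0.0, spec.roi_sd, size=spec.N),
        0.05, 0.95,
    )


def gen_cohort(
    spec: SyntheticSpec,
    n_per_group: int,
    seed: int | None = None,
    with_activity: bool = True,
) -> tuple[list[CohortSubject], list[CohortSubject]]:
    """Two matched synthetic cohorts differing only in E/I balance.

    All subjects share one base anatomy (with per-subject multiplicative
    lognormal jitter on the weights) and one regional excitability profile.
    Group A uses the profile as-is; group B's regional E/I odds are scaled
    by ``1 / (1 - spec.group_shift)``. Each subject gets independently
    drawn edge signs and (optionally) its own Boltzmann-sampled activity
    with continuous noisy observations.
    """
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    ss_base, ss_profile, ss_a, ss_b = master.spawn(4)
    base_seed = int(ss_base.generate_state(1)[0] % (2**31 - 1))
    W_base = gen_structural(spec, seed=base_seed)
    rng_prof = np.random.default_rng(ss_profile.generate_state(2))
    profile_a = _roi_profile(rng_prof, spec)
    profile_b = np.array([_shift_fraction(p, spec.group_shift) for p in profile_a])

    iu = np.triu_indices(spec.N, k=1)

    def _make_group(ss, profile, tag) -> list[CohortSubject]:
        edge_p = 0.5 * (profile[iu[0]] + profile[iu[1]])
        subjects = []
        for k, child in enumerate(ss.spawn(n_per_group)):
            s1, s2, s3, s4 = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in child.spawn(4))
            rng = np.random.default_rng(s1)
            jitter = np.zeros((spec.N, spec.N))
            jitter[iu] = rng.lognormal(mean=0.0, sigma=spec.w_jitter_sd, size=iu[0].size)
            jitter = jitter + jitter.T
            W_s = W_base.W * jitter
            peak = W_s.max()
            if peak > 0:
                W_s = W_s / peak
            W_subj = StructuralConnectome(W_s, list(W_base.region_labels), "max_one")
            J_true = gen_ground_truth_coupling(W_subj, spec, seed=s2, edge_sign_prob=edge_p)
            states = activity = None
            if with_activity:
                states = gen_activity(J_true, spec.beta_true, spec.t_max, seed=s3)
                activity = gen_continuous(states, spec.noise_sd, seed=s4)
            subjects.append(CohortSubject(f"{tag}{k + 1:03d}", W_subj, J_true, states, activity))
        return subjects

    return _make_group(ss_a, profile_a, "A"), _make_group(ss_b, profile_b, "B")
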