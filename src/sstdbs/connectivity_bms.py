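"""Cortico-basal-ganglia model space and random-effects Bayesian model
selection, family inference and Bayesian model averaging.

The model space covers motor inhibition with six nodes — bilateral
inferior frontal gyrus (IFG) and dorsolateral prefrontal cortex (DLPFC),
the medial preSMA/dACC, and the basal ganglia (BG) collapsed into a single
hidden source — wired with 14 extrinsic connections: within-hemisphere
IFG<->DLPFC forward/backward pairs, DLPFC->preSMA feedback, bidirectional
lateral IFG<->BG and preSMA<->BG pairs (the hidden BG node is hierarchically
non-informative), and interhemispheric lateral edges between homologous
regions.  Nine condition-modulation models arise by crossing which cortical
partner's BG connections may change between stimulation conditions
(IFG only, preSMA/dACC only, or both) with the direction of the modulated
edges (afferent to the BG, efferent from it, or both); the three cortical
partners define the three model families.  Intrinsic connections are never
modulated.

Group inference treats the model identity as a random effect across
subjects: a variational Dirichlet posterior over model frequencies is fit to
the per-subject log-evidences, and exceedance probabilities (the chance a
model or family is the most frequent in the population) are estimated by
Monte-Carlo sampling of that posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
import yaml

from .group_stats import PairedResult, paired_compare

__all__ = [
    "Connection",
    "ModelSpace",
    "EvidenceMatrix",
    "BmsResult",
    "FamilyBmsResult",
    "BmaResult",
    "build_model_space",
    "simulate_evidences",
    "simulate_connection_params",
    "rfx_bms",
    "exceedance_from_alpha",
    "family_bms",
    "bma",
]


@dataclass(frozen=True)
class Connection:
    source: str
    target: str
    kind: str  # forward | backward | lateral

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}" if self.kind != "lateral" or self.target != self.source else self.source


#: MNI coordinates of the cortical nodes; the BG source is hidden (no
#: sensor-level projection, hence no coordinate).
NODE_COORDS: dict[str, tuple[float, float, float] | None] = {
    "L_IFG": (-54.0, 12.0, 18.0),
    "R_IFG": (54.0, 12.0, 18.0),
    "L_DLPFC": (-37.0, 27.0, 39.0),
    "R_DLPFC": (37.0, 27.0, 39.0),
    "preSMA_dACC": (0.0, -6.0, 56.0),
    "BG": None,
}


@dataclass(frozen=True)
class ModelSpace:
    """Nodes, connections, the nine modulation models and their families."""

    nodes: tuple[str, ...]
    coords: Mapping[str, tuple[float, float, float] | None]
    connections: tuple[Connection, ...]
    input_nodes: tuple[str, ...]
    models: Mapping[str, tuple[str, ...]]  # model id -> modulated connection names
    families: Mapping[str, tuple[str, ...]]  # family id -> model ids

    def __post_init__(self) -> None:
        if len(self.connections) != 14:
            raise ValueError(f"model space must have 14 connections, got {len(self.connections)}")
        covered = sorted(m for ms in self.families.values() for m in ms)
        if covered != sorted(self.models):
            raise ValueError("families must partition the models")
        bg_edges = {c.name for c in self.connections if "BG" in (c.source, c.target)}
        for mid, mask in self.models.items():
            if not set(mask) <= bg_edges:
                raise ValueError(f"model {mid} modulates a connection not touching the BG")

    @property
    def model_ids(self) -> list[str]:
        return list(self.models)

    @property
    def connection_names(self) -> list[str]:
        return [c.name for c in self.connections]

    def to_yaml(self) -> str:
        doc = {
            "nodes": [
                {"name": n, "mni": list(self.coords[n]) if self.coords[n] else None}
                for n in self.nodes
            ],
            "input_nodes": list(self.input_nodes),
            "connections": [
                {"source": c.source, "target": c.target, "kind": c.kind}
                for c in self.connections
            ],
            "models": {m: list(v) for m, v in self.models.items()},
            "families": {f: list(v) for f, v in self.families.items()},
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpace":
        doc = yaml.safe_load(text)
        return cls(
            nodes=tuple(n["name"] for n in doc["nodes"]),
            coords={
                n["name"]: tuple(n["mni"]) if n["mni"] else None for n in doc["nodes"]
            },
            connections=tuple(
                Connection(c["source"], c["target"], c["kind"])
                for c in doc["connections"]
            ),
            input_nodes=tuple(doc["input_nodes"]),
            models={m: tuple(v) for m, v in doc["models"].items()},
            families={f: tuple(v) for f, v in doc["families"].items()},
        )


def build_model_space() -> ModelSpace:
    """The canonical six-node, 14-connection inhibition model space.

    Visual input enters at the IFG and DLPFC bilaterally.  A fast inhibition
    pathway links the IFG to the BG directly; a slower one runs from the
    DLPFC through the preSMA/dACC to the BG.  Models are named
    ``<partner>_<direction>`` (e.g. ``IFG_efferent`` lets only the BG->IFG
    edges change between stimulation conditions).
    """
    connections = (
        Connection("L_IFG", "L_DLPFC", "forward"),
        Connection("L_DLPFC", "L_IFG", "backward"),
        Connection("R_IFG", "R_DLPFC", "forward"),
        Connection("R_DLPFC", "R_IFG", "backward"),
        Connection("L_DLPFC", "preSMA_dACC", "backward"),
        Connection("R_DLPFC", "preSMA_dACC", "backward"),
        Connection("preSMA_dACC", "BG", "lateral"),
        Connection("BG", "preSMA_dACC", "lateral"),
        Connection("L_IFG", "BG", "lateral"),
        Connection("BG", "L_IFG", "lateral"),
        Connection("R_IFG", "BG", "lateral"),
        Connection("BG", "R_IFG", "lateral"),
        Connection("L_IFG", "R_IFG", "lateral"),
        Connection("L_DLPFC", "R_DLPFC", "lateral"),
    )
    ifg_aff = ("L_IFG->BG", "R_IFG->BG")
    ifg_eff = ("BG->L_IFG", "BG->R_IFG")
    sma_aff = ("preSMA_dACC->BG",)
    sma_eff = ("BG->preSMA_dACC",)
    models = {
        "IFG_afferent": ifg_aff,
        "IFG_efferent": ifg_eff,
        "IFG_both": ifg_aff + ifg_eff,
        "preSMA_afferent": sma_aff,
        "preSMA_efferent": sma_eff,
        "preSMA_both": sma_aff + sma_eff,
        "both_afferent": ifg_aff + sma_aff,
        "both_efferent": ifg_eff + sma_eff,
        "both_both": ifg_aff + ifg_eff + sma_aff + sma_eff,
    }
    families = {
        "IFG": ("IFG_afferent", "IFG_efferent", "IFG_both"),
        "preSMA": ("preSMA_afferent", "preSMA_efferent", "preSMA_both"),
        "both": ("both_afferent", "both_efferent", "both_both"),
    }
    return ModelSpace(
        nodes=tuple(NODE_COORDS),
        coords=dict(NODE_COORDS),
        connections=connections,
        input_nodes=("L_IFG", "R_IFG", "L_DLPFC", "R_DLPFC"),
        models=models,
        families=families,
    )


@dataclass
class EvidenceMatrix:
    """Per-subject, per-model log-evidences (nats)."""

    log_evidence: np.ndarray  # subjects x models
    subject_ids: tuple[str, ...]
    model_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.log_evidence = np.asarray(self.log_evidence, dtype=float)
        n, k = self.log_evidence.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 models")
        if not np.isfinite(self.log_evidence).all():
            raise ValueError("log-evidences must be finite")
        if len(self.subject_ids) != n or len(self.model_ids) != k:
            raise ValueError("id lists must match the matrix shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log_evidence, index=list(self.subject_ids), columns=list(self.model_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceMatrix":
        return cls(df.to_numpy(float), tuple(map(str, df.index)), tuple(map(str, df.columns)))


@dataclass
class BmsResult:
    """Random-effects BMS posterior: Dirichlet concentrations, expected
    model frequencies and Monte-Carlo exceedance probabilities."""

    alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance: np.ndarray
    model_ids: tuple[str, ...]
    converged: bool
    n_iterations: int
    n_samples: int
    seed: int


@dataclass
class FamilyBmsResult:
    model_result: BmsResult
    family_ids: tuple[str, ...]
    family_exceedance: np.ndarray
    family_expected_freq: np.ndarray
    within_family_posterior: Mapping[str, np.ndarray]


@dataclass
class BmaResult:
    """Bayesian model averaging over one family.

    ``subject_strengths`` holds the per-subject averaged log connection
    strengths per condition; ``group_summary`` the per-connection exponential
    of the across-subject mean; ``paired_tests`` the ON vs OFF comparison per
    modulated connection."""

    family: str
    connection_names: tuple[str, ...]
    conditions: tuple[str, ...]
    subject_strengths: np.ndarray  # subjects x connections x conditions
    group_summary: np.ndarray  # connections x conditions
    weights: np.ndarray  # subjects x models-in-family
    paired_tests: list[PairedResult]


def simulate_evidences(
    space: ModelSpace,
    true_model: str,
    effect_nats: float,
    noise_nats: float,
    n_subjects: int,
    heterogeneity: float = 0.0,
    seed: int = 0,
) -> tuple[EvidenceMatrix, list[str]]:
    """Synthetic per-subject log-evidences.

    Each subject's generating model is ``true_model`` with probability
    ``1 - heterogeneity``, otherwise uniform over the rest.  The generating
    model earns ``effect_nats`` of log-evidence over a zero baseline, and
    i.i.d. Normal(0, noise_nats) noise perturbs every cell.  Returns the
    matrix and the per-subject generating models (ground truth).
    """
    if true_model not in space.models:
        raise ValueError(f"unknown model id {true_model!r}")
    if effect_nats < 0 or not 0.0 <= heterogeneity <= 1.0:
        raise ValueError("require effect_nats >= 0 and heterogeneity in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = space.model_ids
    k = len(ids)
    true_idx = ids.index(true_model)
    gen: list[str] = []
    lnE = rng.normal(0.0, noise_nats, (n_subjects, k)) if noise_nats > 0 else np.zeros((n_subjects, k))
    for n in range(n_subjects):
        if rng.random() < heterogeneity:
            others = [i for i in range(k) if i != true_idx]
            g = int(rng.choice(others))
        else:
            g = true_idx
        lnE[n, g] += effect_nats
        gen.append(ids[g])
    subjects = tuple(f"S{i + 1:02d}" for i in range(n_subjects))
    return EvidenceMatrix(lnE, subjects, tuple(ids)), gen


def simulate_connection_params(
    space: ModelSpace,
    n_subjects: int,
    on_scaling: Mapping[str, float] | None = None,
    between_subject_sd: float = 0.3,
    obs_sd: float = 0.05,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Synthetic per-model connection strengths (log scale, nats).

    Each subject draws baseline log-strengths per connection; under the ON
    condition the connections named in ``on_scaling`` are multiplied by the
    given factor (i.e. shifted by its log), but only in models whose
    modulation mask contains that connection — models that hold a connection
    stationary cannot express its change.  Observation noise ``obs_sd`` is
    added per cell.  Returns ``{model_id: subjects x connections x 2}`` with
    condition order (ON, OFF).
    """
    rng = np.random.default_rng(seed)
    on_scaling = dict(on_scaling or {})
    names = space.connection_names
    base = rng.normal(0.0, between_subject_sd, (n_subjects, len(names)))
    out: dict[str, np.ndarray] = {}
    for mid, mask in space.models.items():
        arr = np.empty((n_subjects, len(names), 2))
        for j, cname in enumerate(names):
            off = base[:, j]
            shift = math.log(on_scaling[cname]) if cname in on_scaling and cname in mask else 0.0
            arr[:, j, 0] = off + shift
            arr[:, j, 1] = off
        arr += rng.normal(0.0, obs_sd, arr.shape)
        out[mid] = arr
    return out


def _dirichlet_posterior(
    lnE: np.ndarray, prior: np.ndarray, tol: float = 1e-6, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Variational posterior over model frequencies.

    Iterates the fixed point: subject assignment responsibilities
    ``g_nk ∝ exp(lnE_nk + psi(alpha_k) - psi(sum alpha))`` and
    ``alpha = prior + sum_n g_nk`` until ``max |d alpha| < tol``.  Row-wise
    constants in lnE cancel in the normalisation, giving shift invariance.
    """
    alpha = prior.copy()
    g = np.empty_like(lnE)
    for it in range(1, max_iter + 1):
        logu = lnE + scipy.special.psi(alpha) - scipy.special.psi(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        g = u / u.sum(axis=1, keepdims=True)
        alpha_new = prior + g.sum(axis=0)
        delta = np.abs(alpha_new - alpha).max()
        alpha = alpha_new
        if delta < tol:
            return alpha, g, True, it
    return alpha, g, False, max_iter


def _sample_dirichlet(
    alpha: np.ndarray, n_samples: int, rng: np.random.Generator, chunk: int = 200_000
):
    """Yield Dirichlet(alpha) draws in chunks to bound memory."""
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        yield rng.dirichlet(alpha, size=m)
        remaining -= m


def exceedance_from_alpha(
    alpha: np.ndarray, n_samples: int, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior: the
    per-component probability of being the largest frequency.  Argmax ties
    (probability zero under the continuous posterior, but possible for
    degenerate inputs) are split uniformly."""
    rng = np.random.default_rng(seed)
    alpha = np.asarray(alpha, dtype=float)
    counts = np.zeros(alpha.size)
    for draws in _sample_dirichlet(alpha, n_samples, rng):
        top = draws.max(axis=1, keepdims=True)
        is_top = draws == top
        counts += (is_top / is_top.sum(axis=1, keepdims=True)).sum(axis=0)
    return counts / n_samples


def rfx_bms(
    ev: EvidenceMatrix,
    prior_alpha: float | np.ndarray = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BmsResult:
    """Random-effects Bayesian model selection.

    Fits the variational Dirichlet posterior over population model
    frequencies and estimates per-model exceedance probabilities (the
    probability of being the most frequent model) by Monte-Carlo, with
    argmax ties split uniformly (they occur with probability zero under the
    continuous posterior but matter for degenerate inputs).
    """
    k = len(ev.model_ids)
    prior = np.broadcast_to(np.asarray(prior_alpha, dtype=float), (k,)).copy()
    if (prior <= 0).any():
        raise ValueError("prior_alpha must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    alpha, _g, converged, n_iter = _dirichlet_posterior(ev.log_evidence, prior)
    return BmsResult(
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        exceedance=exceedance_from_alpha(alpha, n_samples, seed),
        model_ids=tuple(ev.model_ids),
        converged=converged,
        n_iterations=n_iter,
        n_samples=n_samples,
        seed=seed,
    )


def family_bms(
    ev: EvidenceMatrix,
    partition: Mapping[str, Sequence[str]],
    prior_alpha: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> FamilyBmsResult:
    """Family-level inference on a partition of the model space.

    The per-model Dirichlet prior is rescaled to ``prior_alpha / |family|``
    so families are a priori equiprobable regardless of size.  Family
    exceedance is the Monte-Carlo probability that the family's summed
    frequency is the largest; within-family posteriors renormalise the
    expected model frequencies inside each family.
    """
    fam_ids = list(partition)
    covered = sorted(m for f in fam_ids for m in partition[f])
    if covered != sorted(ev.model_ids):
        raise ValueError("partition must cover every model exactly once")
    if any(len(partition[f]) == 0 for f in fam_ids):
        raise ValueError("empty family")
    model_ids = list(ev.model_ids)
    prior = np.empty(len(model_ids))
    member = np.zeros((len(fam_ids), len(model_ids)))
    for fi, f in enumerate(fam_ids):
        for m in partition[f]:
            j = model_ids.index(m)
            prior[j] = prior_alpha / len(partition[f])
            member[fi, j] = 1.0

    res = rfx_bms(ev, prior_alpha=prior, n_samples=n_samples, seed=seed)
    rng = np.random.default_rng(seed + 1)
    counts = np.zeros(len(fam_ids))
    for draws in _sample_dirichlet(res.alpha, n_samples, rng):
        fam_p = draws @ member.T
        top = fam_p.max(axis=1, keepdims=True)
        is_top = fam_p == top
        counts += (is_top / is_top.sum(axis=1, keepdims=True)).sum(axis=0)
    fam_freq = member @ res.expected_freq
    within = {
        f: res.expected_freq[member[fi].astype(bool)]
        / res.expected_freq[member[fi].astype(bool)].sum()
        for fi, f in enumerate(fam_ids)
    }
    return FamilyBmsResult(
        model_result=res,
        family_ids=tuple(fam_ids),
        family_exceedance=counts / n_samples,
        family_expected_freq=fam_freq,
        within_family_posterior=within,
    )


def bma(
    subject_params: Mapping[str, np.ndarray],
    ev: EvidenceMatrix,
    family_models: Sequence[str],
    connection_names: Sequence[str],
    conditions: Sequence[str] = ("ON", "OFF"),
    family: str = "",
) -> BmaResult:
    """Bayesian model averaging over one family.

    Per subject, models in the family are weighted by their posterior
    probability (softmax of that subject's log-evidences with a uniform
    within-family prior); connection log-strengths are averaged with those
    weights.  The group summary is the exponential of the across-subject
    mean averaged log-strength; ON vs OFF paired t-tests are run per
    connection.
    """
    family_models = list(family_models)
    for m in family_models:
        if m not in subject_params:
            raise ValueError(f"missing parameters for model {m!r}")
        if m not in ev.model_ids:
            raise ValueError(f"model {m!r} absent from the evidence matrix")
    idx = [list(ev.model_ids).index(m) for m in family_models]
    lnE = ev.log_evidence[:, idx]
    lnE = lnE - lnE.max(axis=1, keepdims=True)
    w = np.exp(lnE)
    w /= w.sum(axis=1, keepdims=True)

    stacked = np.stack([subject_params[m] for m in family_models], axis=0)
    n_models, n_sub, n_conn, n_cond = stacked.shape
    if n_conn != len(connection_names) or n_cond != len(conditions):
        raise ValueError("parameter array shape does not match names/conditions")
    averaged = np.einsum("nm,mnck->nck", w, stacked)
    group = np.exp(averaged.mean(axis=0))

    tests = []
    for j, cname in enumerate(connection_names):
        tests.append(
            paired_compare(
                averaged[:, j, 0], averaged[:, j, 1], test="paired_t", measure=cname
            )
        )
    return BmaResult(
        family=family,
        connection_names=tuple(connection_names),
        conditions=tuple(conditions),
        subject_strengths=averaged,
        group_summary=group,
        weights=w,
        paired_tests=tests,
    )
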