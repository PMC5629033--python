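"""Synthetic AP-MS, TMT, network and annotation inputs with planted truth.

Every generator is a pure function of its configuration and seed, and the
planted ground truth is returned (and serialisable) alongside the data so
recovery experiments need no re-derivation.

Statistical structure emulated:

* AP-MS spectral counts are negative-binomial (overdispersed, as real
  spectral counts are); planted interactors multiply the bait mean by the
  enrichment factor while a configurable fraction is absent from the
  control purification entirely (the "uniquely identified" branch).
  Planted interactors of a nuclear bait are assigned nuclear/unknown
  localization.
* TMT log2 abundances get independent per-channel Gaussian noise with
  stdev sigma_ratio/sqrt(2), so within-group replicate log2 ratios have
  stdev sigma_ratio. The default sigma_ratio = log2(1.3)/1.6449 puts ~90%
  of replicate ratios within +/-1.3-fold — the calibration the threshold
  stage assumes. Planted up/down proteins shift both mutant channels by
  +/-diff_log2fc.
* Functional networks are planted-partition graphs: within-community edge
  scores uniform on [0.6, 1.0], between-community on [0.41, 0.6].
* Annotation tables annotate proteins per term at a base rate; enriched
  terms annotate differential proteins at odds x the base rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    AnnotationTable,
    FunctionalEdge,
    ProteinRecord,
    SpectralCountTable,
    TMTExperiment,
)

__all__ = [
    "DEFAULT_TMT_SIGMA_RATIO",
    "SimulationConfig",
    "PlantedTruth",
    "simulate_apms",
    "simulate_tmt",
    "simulate_network",
    "simulate_annotations",
]

#: sigma of within-group replicate log2 ratios such that the central 90%
#: of a centred Gaussian lies within +/- log2(1.3): log2(1.3)/z(0.95).
DEFAULT_TMT_SIGMA_RATIO = float(math.log2(1.3) / stats.norm.ppf(0.95))  # ~0.23013


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    AP-MS: ``n_proteins`` background proteins with negative-binomial counts
    of mean ``background_mean`` and dispersion ``dispersion`` (variance =
    m + m^2/dispersion); ``n_true_interactors`` planted preys whose bait
    mean is multiplied by ``enrichment_factor`` (>= 4), a fraction
    ``unique_interactor_fraction`` of which have control mean 0.

    TMT: per-protein base log2 abundance ~ Normal(base_log2_mean,
    base_log2_sd) (log-normal abundances); channel noise sd =
    ``tmt_sigma_ratio``/sqrt(2); ``n_diff_up``/``n_diff_down`` proteins
    shifted by +/- ``diff_log2fc`` in both mutant channels.
    """

    n_proteins: int = 500
    n_true_interactors: int = 20
    enrichment_factor: float = 8.0
    background_mean: float = 5.0
    dispersion: float = 10.0
    unique_interactor_fraction: float = 0.25
    tmt_sigma_ratio: float = DEFAULT_TMT_SIGMA_RATIO
    base_log2_mean: float = 10.0
    base_log2_sd: float = 2.0
    n_diff_up: int = 50
    n_diff_down: int = 50
    diff_log2fc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0 <= self.n_true_interactors <= self.n_proteins:
            raise ValueError("n_true_interactors out of range")
        if self.enrichment_factor < 4:
            raise ValueError("enrichment_factor must be >= 4")
        if self.background_mean <= 0 or self.dispersion <= 0:
            raise ValueError("background_mean and dispersion must be positive")
        if not 0 <= self.unique_interactor_fraction <= 1:
            raise ValueError("unique_interactor_fraction must lie in [0, 1]")
        if self.tmt_sigma_ratio <= 0 or self.base_log2_sd <= 0:
            raise ValueError("noise scales must be positive")
        if self.n_diff_up < 0 or self.n_diff_down < 0:
            raise ValueError("planted differential counts must be >= 0")
        if self.n_diff_up + self.n_diff_down > self.n_proteins:
            raise ValueError("planted differential counts exceed n_proteins")
        if self.diff_log2fc < 0:
            raise ValueError("diff_log2fc must be >= 0")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by the generators."""

    interactors: frozenset[str] = frozenset()
    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "interactors": sorted(self.interactors),
            "up": sorted(self.up),
            "down": sorted(self.down),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            interactors=frozenset(payload.get("interactors", [])),
            up=frozenset(payload.get("up", [])),
            down=frozenset(payload.get("down", [])),
        )


def _accessions(n: int, prefix: str = "P") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws via gamma-Poisson; mean 0 gives 0 exactly."""
    mean = np.asarray(mean, dtype=float)
    lam = np.zeros_like(mean)
    positive = mean > 0
    lam[positive] = rng.gamma(shape=dispersion, scale=mean[positive] / dispersion)
    return rng.poisson(lam)


def simulate_apms(
    config: SimulationConfig,
) -> tuple[SpectralCountTable, list[ProteinRecord], PlantedTruth]:
    """Simulate a bait/control AP-MS spectral-count experiment.

    Background proteins draw bait and control counts independently from a
    negative binomial with mean ``background_mean``; planted interactors
    have bait mean multiplied by ``enrichment_factor``. A fraction of the
    planted interactors is absent from the control (mean 0). Lengths are
    uniform on [100, 3000] aa; whole-cell abundance is log-uniform on
    [0.1, 1000] ppm; background localization is {nuclear 0.3, unknown 0.2,
    other 0.5}; planted interactors are nuclear (0.6) or unknown (0.4) and
    always carry >= 2 unique peptides.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accs = _accessions(n)
    planted_idx = np.sort(
        rng.choice(n, size=config.n_true_interactors, replace=False)
    )
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted_idx] = True
    n_unique = int(round(config.unique_interactor_fraction * config.n_true_interactors))
    unique_idx = planted_idx[:n_unique] if n_unique else np.array([], dtype=int)

    bait_mean = np.full(n, config.background_mean)
    bait_mean[planted_mask] *= config.enrichment_factor
    control_mean = np.full(n, config.background_mean)
    control_mean[unique_idx] = 0.0

    bait = _nbinom(rng, bait_mean, config.dispersion)
    control = _nbinom(rng, control_mean, config.dispersion)
    # unique peptides roughly track spectral evidence
    unique_pep = 1 + rng.poisson(bait / 4.0)
    unique_pep[planted_mask] = np.maximum(unique_pep[planted_mask], 2)

    lengths = rng.integers(100, 3001, size=n)
    abundance = 10.0 ** rng.uniform(-1.0, 3.0, size=n)
    localization = rng.choice(
        np.array(["nuclear", "unknown", "other"]), size=n, p=[0.3, 0.2, 0.5]
    )
    localization[planted_mask] = rng.choice(
        np.array(["nuclear", "unknown"]), size=int(planted_mask.sum()), p=[0.6, 0.4]
    )

    counts = SpectralCountTable.from_records(
        (accs[i], int(bait[i]), int(control[i]), int(unique_pep[i])) for i in range(n)
    )
    meta = [
        ProteinRecord(
            accession=accs[i],
            gene_symbol=f"Gene{i + 1}",
            length_aa=int(lengths[i]),
            localization=str(localization[i]),
            abundance_ppm=float(abundance[i]),
        )
        for i in range(n)
    ]
    truth = PlantedTruth(interactors=frozenset(accs[i] for i in planted_idx))
    return counts, meta, truth


def simulate_tmt(config: SimulationConfig) -> tuple[TMTExperiment, PlantedTruth]:
    """Simulate a duplicate control/mutant TMT reporter-abundance matrix.

    Channels are ``control_1``, ``control_2``, ``mutant_1``, ``mutant_2``.
    Each channel observes 2**(base + effect + noise) with per-channel noise
    sd = tmt_sigma_ratio/sqrt(2), so within-group replicate log2 ratios
    have sd ~= tmt_sigma_ratio; planted up/down proteins shift both mutant
    channels by +/- diff_log2fc.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accs = _accessions(n)
    diff_idx = rng.choice(n, size=config.n_diff_up + config.n_diff_down, replace=False)
    up_idx = np.sort(diff_idx[: config.n_diff_up])
    down_idx = np.sort(diff_idx[config.n_diff_up :])

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    effect = np.zeros(n)
    effect[up_idx] = config.diff_log2fc
    effect[down_idx] = -config.diff_log2fc
    sigma_ch = config.tmt_sigma_ratio / math.sqrt(2.0)

    channels = ["control_1", "control_2", "mutant_1", "mutant_2"]
    data = {}
    for ch in channels:
        noise = rng.normal(0.0, sigma_ch, size=n)
        shift = effect if ch.startswith("mutant") else 0.0
        data[ch] = 2.0 ** (base + shift + noise)
    mat = pd.DataFrame(data, index=pd.Index(accs, name="accession"))
    channel_map = {
        "control_1": ("control", 1),
        "control_2": ("control", 2),
        "mutant_1": ("mutant", 1),
        "mutant_2": ("mutant", 2),
    }
    truth = PlantedTruth(
        up=frozenset(accs[i] for i in up_idx),
        down=frozenset(accs[i] for i in down_idx),
    )
    return TMTExperiment(mat, channel_map), truth


def simulate_network(
    n_nodes: int,
    n_clusters: int,
    p_within: float,
    p_between: float,
    seed: int = 0,
) -> tuple[list[FunctionalEdge], dict[str, int]]:
    """Planted-partition functional network with confidence scores.

    Nodes are split into ``n_clusters`` near-equal communities; each
    within-community pair is connected with probability ``p_within`` (score
    uniform on [0.6, 1.0]) and each between-community pair with
    ``p_between`` (score uniform on [0.41, 0.6]). Returns the edge list and
    the planted ``node -> community`` labels.
    """
    if not 0 <= p_between < p_within <= 1 and not (p_within == p_between == 0):
        raise ValueError("require 0 <= p_between < p_within <= 1 (or both 0)")
    rng = np.random.default_rng(seed)
    nodes = _accessions(n_nodes, prefix="N")
    labels = {nodes[i]: i % n_clusters for i in range(n_nodes)}
    edges: list[FunctionalEdge] = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            same = labels[nodes[i]] == labels[nodes[j]]
            p = p_within if same else p_between
            if rng.random() < p:
                lo, hi = (0.6, 1.0) if same else (0.41, 0.6)
                edges.append(
                    FunctionalEdge(nodes[i], nodes[j], float(rng.uniform(lo, hi)))
                )
    return edges, labels


def simulate_annotations(
    background: Sequence[str],
    diff_set: Iterable[str],
    n_terms: int,
    enriched_terms: int,
    odds: float,
    seed: int = 0,
    base_rate: float = 0.05,
) -> tuple[AnnotationTable, frozenset[str]]:
    """Term-to-protein annotations with planted enrichment.

    Each of ``n_terms`` terms annotates background proteins independently
    at ``base_rate``; the first ``enriched_terms`` terms annotate proteins
    in ``diff_set`` at ``min(1, odds * base_rate)`` instead. Returns the
    table plus the planted enriched term ids (``T0001``...).
    """
    if enriched_terms > n_terms:
        raise ValueError("enriched_terms exceeds n_terms")
    if odds < 1:
        raise ValueError("odds must be >= 1")
    background = list(background)
    diff = set(diff_set)
    if not diff <= set(background):
        raise ValueError("diff_set must be a subset of background")
    rng = np.random.default_rng(seed)
    term_ids = _accessions(n_terms, prefix="T")
    enriched = frozenset(term_ids[:enriched_terms])
    records = []
    is_diff = np.array([acc in diff for acc in background])
    p_diff_enriched = min(1.0, odds * base_rate)
    for term_id in term_ids:
        p = np.where(
            is_diff & (term_id in enriched), p_diff_enriched, base_rate
        )
        hits = rng.random(len(background)) < p
        name = "planted process" if term_id in enriched else "background process"
        for acc, hit in zip(background, hits):
            if hit:
                records.append((term_id, name, acc))
    return AnnotationTable.from_records(records), enriched
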