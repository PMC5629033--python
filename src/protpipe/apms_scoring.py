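"""AP-MS interaction-candidate filtering and enrichment-index ranking.

The candidate filter is a conjunction of spectral-count evidence rules:
a protein is retained when it has at least ``min_unique_peptides`` unique
peptides, at least ``min_spectra`` spectra in the bait purification, and is
either uniquely identified (zero control spectra) or enriched at least
``min_fold``-fold over the control purification. Candidates with a nuclear
or unknown subcellular localization are kept, then ranked by enrichment
index

    EI_i = NSAF_i / A_i

where NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j) over all bait-detected
proteins (computed on the full purification, before any filtering) and A_i
is the protein's whole-cell abundance in ppm. High EI flags proteins
captured far above their cellular baseline; the top ``top_k`` are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    LOCALIZATIONS,
    ProteinRecord,
    SpectralCountTable,
    ValidationError,
)

__all__ = [
    "ApmsConfig",
    "InteractionCandidate",
    "compute_nsaf",
    "filter_candidates",
    "filter_localization",
    "rank_by_enrichment_index",
    "score_apms",
]


@dataclass(frozen=True)
class ApmsConfig:
    """Thresholds for the candidate filter cascade and ranking.

    Defaults encode the standard cascade: >= 10 bait spectra, >= 4-fold
    enrichment (or uniquely identified), >= 2 unique peptides, nuclear or
    unknown localization, top 50 by enrichment index. Both count thresholds
    are inclusive.
    """

    min_spectra: int = 10
    min_fold: float = 4.0
    min_unique_peptides: int = 2
    allowed_localizations: frozenset[str] = frozenset({"nuclear", "unknown"})
    top_k: int = 50
    missing_abundance_policy: str = "impute_min"  # or "exclude"

    def __post_init__(self) -> None:
        if self.min_spectra <= 0 or self.min_fold <= 0 or self.min_unique_peptides <= 0:
            raise ValueError("all thresholds must be positive")
        if self.top_k <= 0:
            raise ValueError("top_k must be positive")
        if self.missing_abundance_policy not in ("impute_min", "exclude"):
            raise ValueError(
                f"unknown missing_abundance_policy {self.missing_abundance_policy!r}"
            )
        unknown = set(self.allowed_localizations) - set(LOCALIZATIONS)
        if unknown:
            raise ValueError(f"unknown localization categories: {sorted(unknown)}")
        object.__setattr__(
            self, "allowed_localizations", frozenset(self.allowed_localizations)
        )


@dataclass(frozen=True)
class InteractionCandidate:
    """A retained interaction candidate with its evidence and ranking scores.

    ``fold_enrichment`` is ``None`` for uniquely identified proteins
    (``control_spc == 0``); no pseudocount is ever added.
    ``abundance_imputed`` flags proteins whose whole-cell abundance was
    missing and replaced by the dataset minimum positive abundance.
    """

    accession: str
    bait_spc: int
    control_spc: int
    unique_flag: bool
    fold_enrichment: float | None
    nsaf: float
    enrichment_index: float
    rank: int | None = None
    abundance_imputed: bool = False


def compute_nsaf(
    counts: SpectralCountTable, meta: Sequence[ProteinRecord]
) -> dict[str, float]:
    """Normalized spectral abundance factors over bait-detected proteins.

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j), where the sum runs over
    every protein with bait_spc > 0 (the full affinity purification, before
    any filtering). The values sum to 1 over bait-detected proteins.

    Raises
    ------
    ValidationError
        If a bait-detected accession has no length in ``meta``.
    """
    lengths = {r.accession: r.length_aa for r in meta}
    detected = counts.df[counts.df["bait_spc"] > 0]
    missing = [acc for acc in detected.index if acc not in lengths]
    if missing:
        raise ValidationError(
            f"bait-detected accession(s) missing length metadata: {sorted(missing)}"
        )
    saf = {
        acc: row["bait_spc"] / lengths[acc] for acc, row in detected.iterrows()
    }
    total = sum(saf.values())
    if total == 0:
        return {}
    return {acc: v / total for acc, v in saf.items()}


def filter_candidates(counts: SpectralCountTable, config: ApmsConfig) -> set[str]:
    """Apply the spectral-count evidence filter; returns retained accessions.

    Retained iff unique_peptides >= min_unique_peptides AND
    bait_spc >= min_spectra AND (control_spc == 0 OR
    bait_spc / control_spc >= min_fold). Both thresholds inclusive.
    """
    retained = set()
    for acc, row in counts.df.iterrows():
        bait, control, uniq = row["bait_spc"], row["control_spc"], row["unique_peptides"]
        if uniq < config.min_unique_peptides or bait < config.min_spectra:
            continue
        if control == 0 or bait >= config.min_fold * control:
            retained.add(acc)
    return retained


def filter_localization(
    candidates: Iterable[str], meta: Sequence[ProteinRecord], config: ApmsConfig
) -> set[str]:
    """Keep candidates whose localization is in ``allowed_localizations``."""
    loc = {r.accession: r.localization for r in meta}
    candidates = set(candidates)
    missing = candidates - loc.keys()
    if missing:
        raise ValidationError(
            f"candidate(s) missing localization metadata: {sorted(missing)}"
        )
    return {acc for acc in candidates if loc[acc] in config.allowed_localizations}


def rank_by_enrichment_index(
    candidates: Iterable[str],
    nsaf: Mapping[str, float],
    meta: Sequence[ProteinRecord],
    counts: SpectralCountTable,
    config: ApmsConfig,
) -> list[InteractionCandidate]:
    """Rank candidates by enrichment index and return the top ``top_k``.

    EI = NSAF / abundance_ppm. A missing (or zero) whole-cell abundance is
    handled per ``missing_abundance_policy``: ``impute_min`` substitutes the
    dataset minimum positive abundance and flags the candidate (low-abundance
    proteins with strong capture are exactly the interesting ones);
    ``exclude`` drops such candidates. Sorting is descending by EI with ties
    broken by accession ascending; ranks are 1..k.
    """
    by_acc = {r.accession: r for r in meta}
    candidates = set(candidates)
    missing_meta = candidates - by_acc.keys()
    if missing_meta:
        raise ValidationError(f"candidate(s) missing metadata: {sorted(missing_meta)}")
    missing_nsaf = candidates - set(nsaf)
    if missing_nsaf:
        raise ValidationError(f"candidate(s) missing NSAF: {sorted(missing_nsaf)}")

    positive = [
        r.abundance_ppm
        for r in meta
        if r.abundance_ppm is not None and r.abundance_ppm > 0
    ]
    min_positive = min(positive) if positive else None

    scored: list[InteractionCandidate] = []
    for acc in candidates:
        rec = by_acc[acc]
        abundance = rec.abundance_ppm
        imputed = False
        if abundance is None or abundance == 0:
            if config.missing_abundance_policy == "exclude":
                continue
            if min_positive is None:
                raise ValidationError(
                    "cannot impute missing abundance: no positive abundances in dataset"
                )
            abundance = min_positive
            imputed = True
        row = counts.df.loc[acc]
        bait, control = int(row["bait_spc"]), int(row["control_spc"])
        scored.append(
            InteractionCandidate(
                accession=acc,
                bait_spc=bait,
                control_spc=control,
                unique_flag=control == 0,
                fold_enrichment=None if control == 0 else bait / control,
                nsaf=float(nsaf[acc]),
                enrichment_index=float(nsaf[acc]) / abundance,
                abundance_imputed=imputed,
            )
        )
    scored.sort(key=lambda c: (-c.enrichment_index, c.accession))
    top = scored[: config.top_k]
    return [
        InteractionCandidate(**{**c.__dict__, "rank": i + 1}) for i, c in enumerate(top)
    ]


def score_apms(
    counts: SpectralCountTable,
    meta: Sequence[ProteinRecord],
    config: ApmsConfig | None = None,
) -> list[InteractionCandidate]:
    """Run the full cascade: NSAF, count filter, localization filter, ranking."""
    config = config or ApmsConfig()
    nsaf = compute_nsaf(counts, meta)
    retained = filter_candidates(counts, config)
    localized = filter_localization(retained, meta, config)
    return rank_by_enrichment_index(localized, nsaf, meta, counts, config)
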