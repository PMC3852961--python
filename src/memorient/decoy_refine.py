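"""Combined refinement energy and decoy-discrimination statistics.

The membrane term is combined with an externally supplied constraint
energy as ``E_total = E_contact + w * E_membrane`` with the weight ``w``
restricted to [0.1, 2.0] (default 1.6).  The contact term and TM-scores
are inputs, never computed here; this module is the scoring hook a
fragment-recombination refiner would call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .potential import PotentialTable
from .search import SearchConfig, orient
from .structure_io import Structure, read_structure

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_WEIGHT",
    "WEIGHT_RANGE",
    "DecoyRecord",
    "DiscriminationReport",
    "combined_energy",
    "score_ensemble",
    "discrimination_stats",
    "read_ensemble_manifest",
]

DEFAULT_WEIGHT = 1.6
WEIGHT_RANGE = (0.1, 2.0)


def combined_energy(e_contact: float, e_membrane: float,
                    w: float = DEFAULT_WEIGHT) -> float:
    """``e_contact + w * e_membrane`` with ``w`` restricted to [0.1, 2.0]."""
    if not (WEIGHT_RANGE[0] <= w <= WEIGHT_RANGE[1]):
        raise ValueError(f"weight must be in [{WEIGHT_RANGE[0]}, {WEIGHT_RANGE[1]}]")
    if not (math.isfinite(e_contact) and math.isfinite(e_membrane)):
        raise ValueError("energies must be finite")
    return e_contact + w * e_membrane


@dataclass(frozen=True)
class DecoyRecord:
    model_id: str
    e_membrane: float
    e_contact: float | None = None
    tm_score: float | None = None


@dataclass
class DiscriminationReport:
    ranking: list[str]  # model ids, ascending membrane energy
    native_rank: int
    native_in_top10: bool
    pearson_r: float | None
    min_tm: float | None
    max_tm: float | None


REFINEMENT_POP_SIZE = 500  # reduced GA pool for ensemble scoring


def default_scoring_config(seed: int = 0) -> SearchConfig:
    return SearchConfig(method="ga", pop_size=REFINEMENT_POP_SIZE, n_runs=2,
                        generations=40, hj_polish=True, seed=seed)


def _model_seed(global_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=global_seed,
                                      spawn_key=(index,)).generate_state(1)[0])


def score_ensemble(models: Sequence[tuple[str, Structure]], table: PotentialTable,
                   cfg: SearchConfig | None = None, seed: int = 0,
                   tm_scores: dict[str, float] | None = None,
                   e_contacts: dict[str, float] | None = None) -> list[DecoyRecord]:
    """Orient every model with the reduced-pool GA and record its
    minimised membrane energy.

    Per-model seeds are derived from ``(seed, model index)`` so a rerun
    of the same ensemble is bit-reproducible.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    cfg = cfg or default_scoring_config()
    tm_scores = tm_scores or {}
    e_contacts = e_contacts or {}
    records = []
    for index, (model_id, structure) in enumerate(models):
        sub = replace(cfg, seed=_model_seed(seed, index))
        try:
            result, _ = orient(structure, table, sub)
        except ValueError as exc:
            logger.warning("skipping model %s: %s", model_id, exc)
            continue
        records.append(DecoyRecord(model_id=model_id, e_membrane=result.energy,
                                   e_contact=e_contacts.get(model_id),
                                   tm_score=tm_scores.get(model_id)))
    return records


def discrimination_stats(records: Sequence[DecoyRecord],
                         native_id: str) -> DiscriminationReport:
    """Rank by ascending membrane energy (ties by model id) and report
    the native rank, top-10 membership and Pearson's r against TM-score."""
    ids = {r.model_id for r in records}
    if native_id not in ids:
        raise ValueError(f"native id {native_id!r} not in records")
    ranked = sorted(records, key=lambda r: (r.e_membrane, r.model_id))
    ranking = [r.model_id for r in ranked]
    native_rank = ranking.index(native_id) + 1

    pairs = [(r.e_membrane, r.tm_score) for r in records if r.tm_score is not None]
    pearson_r: float | None = None
    if len(pairs) >= 3:
        e, tm = zip(*pairs)
        if np.std(e) > 0 and np.std(tm) > 0:
            pearson_r = float(stats.pearsonr(e, tm).statistic)
    tms = [r.tm_score for r in records if r.tm_score is not None]
    return DiscriminationReport(
        ranking=ranking,
        native_rank=native_rank,
        native_in_top10=native_rank <= 10,
        pearson_r=pearson_r,
        min_tm=min(tms) if tms else None,
        max_tm=max(tms) if tms else None,
    )


def read_ensemble_manifest(text: str, base_dir: str | Path | None = None
                           ) -> tuple[list[tuple[str, Structure]], dict[str, float], dict[str, float]]:
    """Parse an ensemble TSV (``model_path  [e_contact]  [tm_score]``) and
    load the models; returns (models, e_contacts, tm_scores)."""
    base = Path(base_dir) if base_dir else None
    models: list[tuple[str, Structure]] = []
    e_contacts: dict[str, float] = {}
    tm_scores: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        path = Path(fields[0])
        if base and not path.is_absolute():
            path = base / path
        model_id = path.stem
        try:
            structure = read_structure(path.read_text(), structure_id=model_id)
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable model %s: %s", path, exc)
            continue
        models.append((model_id, structure))
        if len(fields) > 1 and fields[1] not in ("", "-"):
            e_contacts[model_id] = float(fields[1])
        if len(fields) > 2 and fields[2] not in ("", "-"):
            tm_scores[model_id] = float(fields[2])
    return models, e_contacts, tm_scores
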