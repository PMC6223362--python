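"""The 3D sliding-window engine.

For every polymer residue in scope, the engine collects all residues within
the configured radius (the spatial window), assembles the alignment columns
or numeric values mapped to those residues, applies a scoring function, and
reports the result at the window's central residue. Scores are computed for
every residue — including residues with no data of their own — as long as
the window contains at least ``min_data`` mapped residues; otherwise the
score is null (None), which downstream output renders as a missing value.

When several chains map to the same reference positions (homo-oligomers),
each chain's residues are scored independently and a window spanning both
protomers contributes each mapped residue's columns once per residue, so
shared reference positions are counted once per distinct residue.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

from .errors import InputError, LowIdentityError, ScoringError
from .popgen import diversity_summary, shannon_entropy
from .seqalign import (
    AlignmentData,
    GapPolicy,
    NumericTable,
    ReferenceSeq,
    ResidueDataMap,
    align_protein_to_reference,
    compose_map,
    map_codons,
    map_protein_columns,
    window_subalignment,
)
from .spatial import NeighborQueryConfig, build_neighbor_index, neighbors_within
from .structures import ResidueId, Structure, polymer_sequence, write_bfactor_pdb

logger = logging.getLogger(__name__)

DataKind = Literal["dna-alignment", "protein-alignment", "numeric"]


@dataclass(frozen=True)
class ScoringFunction:
    """A window scorer: sub-alignment (or numeric values) → number or None.

    ``kind`` declares the input the function understands; ``min_data`` is the
    minimum number of mapped residues a window needs before the function is
    called at all (windows below it score null).
    """

    name: str
    kind: DataKind
    fn: Callable[..., float | None]
    min_data: int = 1

    def with_min_data(self, min_data: int) -> "ScoringFunction":
        return ScoringFunction(self.name, self.kind, self.fn, min_data=min_data)


def _score_if_columns(metric: Callable[[AlignmentData], float | None]):
    def scorer(sub: AlignmentData) -> float | None:
        if sub.length == 0:
            return None
        return metric(sub)

    return scorer


BUILTIN_FUNCTIONS: dict[str, ScoringFunction] = {
    "tajimas-d": ScoringFunction(
        "tajimas-d", "dna-alignment", _score_if_columns(lambda s: diversity_summary(s).tajimas_d)
    ),
    "pi": ScoringFunction(
        "pi", "dna-alignment", _score_if_columns(lambda s: diversity_summary(s).pi_total)
    ),
    "theta-w": ScoringFunction(
        "theta-w", "dna-alignment", _score_if_columns(lambda s: diversity_summary(s).theta_w)
    ),
    "seg-sites": ScoringFunction(
        "seg-sites", "dna-alignment", _score_if_columns(lambda s: float(diversity_summary(s).S))
    ),
    "entropy": ScoringFunction("entropy", "protein-alignment", shannon_entropy),
    "mean": ScoringFunction("mean", "numeric", lambda values: float(np.mean(values))),
}


def get_function(name: str, min_data: int = 1) -> ScoringFunction:
    try:
        fn = BUILTIN_FUNCTIONS[name]
    except KeyError:
        raise InputError(
            f"unknown function {name!r}; built-ins: {sorted(BUILTIN_FUNCTIONS)}"
        ) from None
    return fn.with_min_data(min_data) if min_data != 1 else fn


def _data_kind(data: AlignmentData | NumericTable) -> DataKind:
    if isinstance(data, NumericTable):
        return "numeric"
    return "dna-alignment" if data.alphabet == "dna" else "protein-alignment"


@dataclass
class WindowResult:
    """Per-residue scores plus the configuration that produced them."""

    scores: dict[ResidueId, float | None]
    window_sizes: dict[ResidueId, int]
    config: dict = field(default_factory=dict)

    def __getitem__(self, rid: ResidueId) -> float | None:
        return self.scores[rid]

    def defined(self) -> dict[ResidueId, float]:
        return {rid: v for rid, v in self.scores.items() if v is not None}


def build_residue_map(
    structure: Structure,
    data: AlignmentData | NumericTable,
    ref: ReferenceSeq,
    chains: str | Sequence[str] = "all",
    min_identity: float = 0.30,
    representative: int = 0,
) -> ResidueDataMap:
    """Structure → reference → data-column correspondence for ``data``.

    Each selected chain is aligned to the reference independently, so every
    protomer of a homo-oligomer receives its own mapping to the shared
    reference positions. With several chains selected, chains below the
    identity floor are left unmapped (with a warning); with a single chain,
    or when no chain maps, the failure propagates.
    """
    if chains == "all":
        chain_ids = list(structure.chains.keys())
    elif isinstance(chains, str):
        chain_ids = [chains]
    else:
        chain_ids = list(chains)
    residue_to_ref: dict[ResidueId, int] = {}
    failures: list[str] = []
    for cid in chain_ids:
        seq, index = polymer_sequence(structure, cid)
        if not seq:
            continue
        try:
            residue_to_ref.update(
                align_protein_to_reference(seq, index, ref, min_identity=min_identity)
            )
        except LowIdentityError as exc:
            if len(chain_ids) == 1:
                raise
            failures.append(f"chain {cid}: {exc}")
    if not residue_to_ref:
        raise LowIdentityError(
            "no selected chain aligns to the reference ("
            + "; ".join(failures) + ")"
        )
    for msg in failures:
        logger.warning("unmapped %s", msg)
    if isinstance(data, NumericTable):
        ref_to_columns = {p: (p,) for p in data.values}
        strand = None
    elif data.alphabet == "dna":
        ref_to_columns, strand = map_codons(
            ref, data, representative=representative, min_identity=min_identity
        )
    else:
        ref_to_columns = map_protein_columns(
            ref, data, representative=representative, min_identity=min_identity
        )
        strand = None
    return compose_map(residue_to_ref, ref_to_columns, strand=strand)


def run_window_analysis(
    structure: Structure,
    data: AlignmentData | NumericTable,
    ref: ReferenceSeq,
    fn: ScoringFunction | str,
    config: NeighborQueryConfig,
    gap_policy: GapPolicy = "complete-deletion",
    chains: str | Sequence[str] = "all",
    min_identity: float = 0.30,
    representative: int = 0,
) -> WindowResult:
    """Run the full 3D sliding-window analysis.

    Deterministic: identical inputs give identical results. Raises
    :class:`InputError` if the scoring function's kind does not match the
    data, and propagates alignment/mapping failures with context.
    """
    if isinstance(fn, str):
        fn = get_function(fn)
    kind = _data_kind(data)
    if fn.kind != kind:
        raise InputError(
            f"scoring function {fn.name!r} expects {fn.kind} data but the input is {kind}"
        )
    rmap = build_residue_map(
        structure, data, ref,
        chains=chains, min_identity=min_identity, representative=representative,
    )
    _, index_ids = polymer_sequence(structure, chains)
    spatial_index = build_neighbor_index(structure, config)

    scores: dict[ResidueId, float | None] = {}
    window_sizes: dict[ResidueId, int] = {}
    for center in index_ids:
        window = neighbors_within(spatial_index, center, config)
        window_sizes[center] = len(window)
        mapped = [rid for rid in window if rmap.columns_for(rid) is not None]
        if len(mapped) < fn.min_data:
            scores[center] = None
            continue
        try:
            if isinstance(data, NumericTable):
                values = [data.values[rmap.residue_to_ref[rid]] for rid in sorted(mapped)]
                score = fn.fn(values)
            else:
                sub = window_subalignment(data, rmap, window, gap_policy=gap_policy)
                score = fn.fn(sub)
        except Exception as exc:  # noqa: BLE001 - re-raise with window context
            raise ScoringError(
                f"scoring function {fn.name!r} failed at central residue {center} "
                f"(window of {len(window)}): {exc}"
            ) from exc
        scores[center] = None if score is None else float(score)

    snapshot = {
        "radius": config.radius,
        "metric": config.metric,
        "chain_scope": config.chain_scope,
        "include_hetero": config.include_hetero,
        "include_hydrogens": config.include_hydrogens,
        "gap_policy": gap_policy,
        "function": fn.name,
        "min_data": fn.min_data,
        "chains": chains if isinstance(chains, str) else list(chains),
        "strand": rmap.strand,
        "duplicate_columns_across_protomers": "included",
    }
    return WindowResult(scores=scores, window_sizes=window_sizes, config=snapshot)


# ---------------------------------------------------------------------------
# export


def _rid_row(rid: ResidueId, result: WindowResult) -> dict:
    score = result.scores[rid]
    return {
        "chain": rid.chain,
        "number": rid.number,
        "icode": rid.icode,
        "score": score,
        "window_size": result.window_sizes.get(rid),
    }


def write_tsv(result: WindowResult, path: str | os.PathLike) -> None:
    """TSV export: chain, resnum, icode, score (empty for null), window_size."""
    lines = ["chain\tresnum\ticode\tscore\twindow_size"]
    for rid in sorted(result.scores):
        row = _rid_row(rid, result)
        score = "" if row["score"] is None else repr(row["score"])
        lines.append(f"{row['chain']}\t{row['number']}\t{row['icode']}\t{score}\t{row['window_size']}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_json(result: WindowResult, path: str | os.PathLike) -> None:
    """JSON export: config snapshot plus the ordered residue/score records."""
    payload = {
        "config": result.config,
        "residues": [_rid_row(rid, result) for rid in sorted(result.scores)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json_scores(path: str | os.PathLike) -> dict[ResidueId, float | None]:
    """Re-import the score map written by :func:`write_json`."""
    with open(path) as fh:
        payload = json.load(fh)
    return {
        ResidueId(r["chain"], r["number"], r["icode"]): r["score"]
        for r in payload["residues"]
    }


def export_results(
    result: WindowResult,
    structure: Structure | None = None,
    tsv_path: str | os.PathLike | None = None,
    json_path: str | os.PathLike | None = None,
    pdb_path: str | os.PathLike | None = None,
    missing_value: float = 0.0,
) -> None:
    """Write any combination of TSV, JSON and B-factor-annotated PDB output."""
    if tsv_path is not None:
        write_tsv(result, tsv_path)
    if json_path is not None:
        write_json(result, json_path)
    if pdb_path is not None:
        if structure is None:
            raise InputError("PDB export requires the structure")
        write_bfactor_pdb(structure, result.scores, pdb_path, missing_value=missing_value)
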