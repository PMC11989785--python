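"""Ligand-receptor crosstalk inference between co-cultured cell populations.

Differentially expressed ligands and receptors are screened against a
curated ligand-receptor database, paired under explicit direction rules,
and ranked by a communication score (CS): the product of the two members'
fold-change magnitudes, CS = 2^|log2FC_ligand| * 2^|log2FC_receptor|.

Two pairing methods are supported:

* method 1 compares each cell type's monoculture against its co-culture —
  autocrine pairs draw ligand and receptor from the same cell's contrast;
  paracrine pairs take upregulated ligands from the source cell's contrast
  and downregulated receptors from the target cell's contrast;
* method 2 uses the co-culture vs co-culture contrast (CO-IMAdC vs CO-SMSC)
  for both members — genes higher in co-cultured IMAdCs are UP, genes
  higher in co-cultured SMSCs are DOWN, so direction encodes which cell
  expresses the gene.

All eight default rules are plain data and user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import ContrastResult
from .io_formats import LRDatabase
from .simulate import CO_CONTRAST, IMADC_CONTRAST, SMSC_CONTRAST

PAIR_COLUMNS = [
    "mode",
    "method",
    "source_cell",
    "target_cell",
    "ligand",
    "receptor",
    "ligand_log2fc",
    "receptor_log2fc",
    "fc_ligand",
    "fc_receptor",
    "cs",
    "rank",
]


@dataclass(frozen=True)
class LRCandidateSets:
    """Differentially expressed ligands/receptors of one contrast."""

    contrast: str
    ligands: pd.DataFrame  # index symbol; columns log2fc, padj, status
    receptors: pd.DataFrame

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    @property
    def n_receptors(self) -> int:
        return len(self.receptors)


@dataclass(frozen=True)
class DirectionRule:
    """Which contrast and DE direction each member of a pair must satisfy."""

    mode: str  # autocrine | paracrine
    method: int  # 1 | 2
    ligand_contrast: str
    ligand_status_required: str  # UP | DOWN | ANY
    receptor_contrast: str
    receptor_status_required: str
    source_cell: str
    target_cell: str

    def __post_init__(self) -> None:
        if self.mode not in ("autocrine", "paracrine"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.method not in (1, 2):
            raise ValueError(f"invalid method {self.method!r}")
        for status in (self.ligand_status_required, self.receptor_status_required):
            if status not in ("UP", "DOWN", "ANY"):
                raise ValueError(f"invalid status requirement {status!r}")
        if self.mode == "autocrine" and self.source_cell != self.target_cell:
            raise ValueError("autocrine rules need source_cell == target_cell")


def default_rules(
    imadc_contrast: str = IMADC_CONTRAST,
    smsc_contrast: str = SMSC_CONTRAST,
    co_contrast: str = CO_CONTRAST,
) -> list[DirectionRule]:
    """The eight default rules of the two-method autocrine/paracrine search.

    Method-1 autocrine searches each cell's own mono-vs-co contrast with no
    direction constraint.  Method-2 autocrine requires UP+UP (IMAdC) or
    DOWN+DOWN (SMSC) in the co-vs-co contrast, whose log2FC numerator is the
    co-cultured IMAdC group.  Method-1 paracrine pairs upregulated ligands
    of the source cell's contrast with downregulated receptors of the
    target cell's contrast; method-2 paracrine encodes source/target via
    direction in the co-vs-co contrast.
    """
    return [
        DirectionRule("autocrine", 1, imadc_contrast, "ANY", imadc_contrast, "ANY", "IMAdC", "IMAdC"),
        DirectionRule("autocrine", 1, smsc_contrast, "ANY", smsc_contrast, "ANY", "SMSC", "SMSC"),
        DirectionRule("autocrine", 2, co_contrast, "UP", co_contrast, "UP", "IMAdC", "IMAdC"),
        DirectionRule("autocrine", 2, co_contrast, "DOWN", co_contrast, "DOWN", "SMSC", "SMSC"),
        DirectionRule("paracrine", 1, smsc_contrast, "UP", imadc_contrast, "DOWN", "SMSC", "IMAdC"),
        DirectionRule("paracrine", 1, imadc_contrast, "UP", smsc_contrast, "DOWN", "IMAdC", "SMSC"),
        DirectionRule("paracrine", 2, co_contrast, "DOWN", co_contrast, "UP", "SMSC", "IMAdC"),
        DirectionRule("paracrine", 2, co_contrast, "UP", co_contrast, "DOWN", "IMAdC", "SMSC"),
    ]


def select_lr_candidates(result: ContrastResult, db: LRDatabase) -> LRCandidateSets:
    """DEGs of one contrast that appear as ligands/receptors in the database.

    A gene annotated as both ligand and receptor lands in both sets.
    """
    de = result.table[result.table["status"].isin(["UP", "DOWN"])]
    cols = ["log2fc", "padj", "status"]
    ligands = de.loc[de.index.isin(db.ligands), cols].sort_index()
    receptors = de.loc[de.index.isin(db.receptors), cols].sort_index()
    return LRCandidateSets(result.name, ligands, receptors)


def communication_score(ligand_log2fc: float, receptor_log2fc: float) -> tuple[float, float, float]:
    """Magnitude fold changes and their product.

    fc = 2^|log2fc| for each member; CS = fc_ligand * fc_receptor.  Using
    magnitudes keeps strongly downregulated members high-ranking instead of
    collapsing them toward zero.
    """
    if not (np.isfinite(ligand_log2fc) and np.isfinite(receptor_log2fc)):
        raise ValueError("log2 fold changes must be finite")
    fc_l = float(2.0 ** abs(ligand_log2fc))
    fc_r = float(2.0 ** abs(receptor_log2fc))
    return fc_l, fc_r, fc_l * fc_r


def _status_ok(status: str, required: str) -> bool:
    return required == "ANY" or status == required


def build_pairs(
    rule: DirectionRule,
    candidates: dict[str, LRCandidateSets],
    db: LRDatabase,
) -> pd.DataFrame:
    """All database pairs whose members satisfy the rule, scored but unranked."""
    for contrast in (rule.ligand_contrast, rule.receptor_contrast):
        if contrast not in candidates:
            raise ValueError(f"rule references unknown contrast {contrast!r}")
    lig_set = candidates[rule.ligand_contrast].ligands
    rec_set = candidates[rule.receptor_contrast].receptors

    rows = []
    for lig, rec in sorted(db.pairs):
        if lig not in lig_set.index or rec not in rec_set.index:
            continue
        if not _status_ok(lig_set.at[lig, "status"], rule.ligand_status_required):
            continue
        if not _status_ok(rec_set.at[rec, "status"], rule.receptor_status_required):
            continue
        l_lfc = float(lig_set.at[lig, "log2fc"])
        r_lfc = float(rec_set.at[rec, "log2fc"])
        fc_l, fc_r, cs = communication_score(l_lfc, r_lfc)
        rows.append(
            {
                "mode": rule.mode,
                "method": rule.method,
                "source_cell": rule.source_cell,
                "target_cell": rule.target_cell,
                "ligand": lig,
                "receptor": rec,
                "ligand_log2fc": l_lfc,
                "receptor_log2fc": r_lfc,
                "fc_ligand": fc_l,
                "fc_receptor": fc_r,
                "cs": cs,
            }
        )
    table = pd.DataFrame(rows, columns=[c for c in PAIR_COLUMNS if c != "rank"])
    return table.drop_duplicates(subset=["ligand", "receptor"]).reset_index(drop=True)


def rank_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Sort by CS descending, ties by (ligand, receptor); ranks 1..n."""
    if pairs.empty:
        out = pairs.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    out = pairs.sort_values(
        ["cs", "ligand", "receptor"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def _assert_sound(table: pd.DataFrame, candidates: dict[str, LRCandidateSets], db: LRDatabase) -> None:
    # soundness invariant checked on every run: emitted pairs are in the db
    # and both members are DEGs somewhere among the rule contrasts
    for row in table.itertuples(index=False):
        assert (row.ligand, row.receptor) in db.pairs, "pair not in database"
        assert any(
            row.ligand in c.ligands.index for c in candidates.values()
        ), "ligand not a DE candidate"
        assert any(
            row.receptor in c.receptors.index for c in candidates.values()
        ), "receptor not a DE candidate"


def run_crosstalk(
    results: dict[str, ContrastResult],
    db: LRDatabase,
    rules: list[DirectionRule] | None = None,
) -> pd.DataFrame:
    """Execute all direction rules, rank within each stratum, concatenate.

    ``results`` maps contrast name -> classified ContrastResult and must
    contain every contrast the rules reference.  A stratum is one
    (mode, method, source_cell, target_cell) combination; ranking is within
    stratum because each corresponds to one panel of the study's report.
    """
    rules = rules if rules is not None else default_rules()
    needed = {r.ligand_contrast for r in rules} | {r.receptor_contrast for r in rules}
    missing = needed - set(results)
    if missing:
        raise ValueError(f"missing contrast result(s): {sorted(missing)}")

    candidates = {name: select_lr_candidates(res, db) for name, res in results.items()}
    chunks = []
    for rule in rules:
        pairs = build_pairs(rule, candidates, db)
        if len(pairs):
            chunks.append(rank_pairs(pairs))
    table = (
        pd.concat(chunks, ignore_index=True)[PAIR_COLUMNS]
        if chunks
        else pd.DataFrame(columns=PAIR_COLUMNS)
    )
    _assert_sound(table, candidates, db)
    return table
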