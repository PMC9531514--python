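"""Ligand-table ingestion, conformer generation and SDF I/O.

This is the production (real-chemistry) front end: read a ligand table
(ligand ID, SMILES, target label, optional IC50-style activity),
canonicalize and deduplicate structures within each target, embed 3D
conformer ensembles, and round-trip conformers through SDF V2000.

RDKit is imported lazily so the synthetic pipeline path stays importable
without a chemistry toolkit.  Conformers come from RDKit's ETKDG
distance-geometry embedding followed by an MMFF94 energy-minimization
pass; the ensemble is deterministic for a fixed seed.  Activity values
are carried as metadata only — class membership is taken as given by the
input table, with no activity cutoff applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .errors import InputError, SchemaError

logger = logging.getLogger(__name__)

_COLUMN_ALIASES = {
    "ligand_id": {"ligand_id", "molecule name", "molecule_name", "chembl_id", "id", "name"},
    "smiles": {"smiles", "canonical_smiles"},
    "target": {"target", "target_label", "target_name"},
    "activity": {"activity", "ic50", "ic50_nm", "standard_value"},
}

DEFAULT_CONFORMERS_PER_LIGAND = 16


def _require_rdkit():
    try:
        from rdkit import Chem  # noqa: F401

        return Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the real-chemistry path requires rdkit; "
            "install kld-dti[chem] or use the synthetic pipeline"
        ) from exc


@dataclass
class LigandRecord:
    """One ligand-target association from the input table."""

    ligand_id: str
    smiles: str
    target_label: str
    activity: float | None = None
    canonical_smiles: str = ""


@dataclass
class ConformerSet:
    """A ligand's 3D conformer ensemble (one RDKit mol per conformer)."""

    ligand_id: str
    mols: list  # rdkit.Chem.Mol, each with exactly one 3D conformer

    def __post_init__(self) -> None:
        if not self.mols:
            raise InputError(f"ligand {self.ligand_id!r} has no conformers")

    @property
    def n_conformers(self) -> int:
        return len(self.mols)


def _normalize_columns(columns) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        for canon, aliases in _COLUMN_ALIASES.items():
            if key in aliases and canon not in mapping:
                mapping[canon] = col
    return mapping


def read_ligand_table(path: str | Path, format: str | None = None) -> list[LigandRecord]:
    """Read, canonicalize and deduplicate a CSV/TSV ligand table.

    Rows with unparsable SMILES are reported and dropped.  Duplicates —
    the same canonical structure under the same target — keep the
    first-seen record; the same structure under two different targets
    yields one record per target.
    """
    import pandas as pd

    Chem = _require_rdkit()
    path = Path(path)
    if not path.exists():
        raise InputError(f"ligand table not found: {path}")
    sep = {"csv": ",", "tsv": "\t"}.get(
        format or path.suffix.lstrip(".").lower(), ","
    )
    df = pd.read_csv(path, sep=sep)
    mapping = _normalize_columns(df.columns)
    missing = [c for c in ("ligand_id", "smiles", "target") if c not in mapping]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )

    records: list[LigandRecord] = []
    seen: set[tuple[str, str]] = set()
    n_bad = n_dup = 0
    for _, row in df.iterrows():
        smiles = str(row[mapping["smiles"]])
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            n_bad += 1
            logger.warning("dropping unparsable SMILES %r (%s)", smiles,
                           row[mapping["ligand_id"]])
            continue
        canonical = Chem.MolToSmiles(mol)
        target = str(row[mapping["target"]])
        key = (canonical, target)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        activity = None
        if "activity" in mapping and pd.notna(row[mapping["activity"]]):
            activity = float(row[mapping["activity"]])
        records.append(
            LigandRecord(
                ligand_id=str(row[mapping["ligand_id"]]),
                smiles=smiles,
                target_label=target,
                activity=activity,
                canonical_smiles=canonical,
            )
        )
    if not records:
        raise InputError(f"{path}: no valid ligand records after parsing")
    per_target = {}
    for r in records:
        per_target[r.target_label] = per_target.get(r.target_label, 0) + 1
    logger.info(
        "read %d ligands (%d unparsable dropped, %d duplicates removed); "
        "per-target counts: %s",
        len(records), n_bad, n_dup, per_target,
    )
    return records


def deduplicate(records: list[LigandRecord]) -> list[LigandRecord]:
    """Remove repeated (canonical structure, target) pairs, keeping the
    first-seen record.  Idempotent."""
    Chem = _require_rdkit()
    seen: set[tuple[str, str]] = set()
    out = []
    for r in records:
        canonical = r.canonical_smiles
        if not canonical:
            mol = Chem.MolFromSmiles(r.smiles)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
        key = (canonical, r.target_label)
        if key not in seen:
            seen.add(key)
            out.append(
                LigandRecord(r.ligand_id, r.smiles, r.target_label,
                             r.activity, canonical)
            )
    return out


def generate_conformers(
    record: LigandRecord,
    n_conf: int = DEFAULT_CONFORMERS_PER_LIGAND,
    seed: int = 0,
) -> ConformerSet:
    """Embed up to ``n_conf`` distinct 3D conformers for one ligand.

    ETKDG distance-geometry embedding with an MMFF94 minimization pass;
    near-duplicate conformers are pruned by RMSD.  Deterministic for a
    fixed seed.  Embedding failure raises :class:`InputError` so the
    caller can flag the ligand and continue.
    """
    Chem = _require_rdkit()
    from rdkit.Chem import AllChem

    if n_conf < 1:
        raise InputError("n_conf must be >= 1")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES for {record.ligand_id!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1) or 1
    params.pruneRmsThresh = 0.5
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conf, params=params)
    if not conf_ids:
        raise InputError(f"conformer embedding failed for {record.ligand_id!r}")
    try:
        AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=200)
    except Exception:  # some structures lack MMFF parameters; keep raw geometry
        logger.warning("MMFF minimization failed for %s; keeping ETKDG "
                       "geometry", record.ligand_id)
    mol = Chem.RemoveHs(mol)
    mols = []
    for cid in conf_ids:
        single = Chem.Mol(mol, confId=int(cid))
        single.SetProp("_Name", record.ligand_id)
        mols.append(single)
    return ConformerSet(ligand_id=record.ligand_id, mols=mols)


def write_sdf(sets: list[ConformerSet], path: str | Path) -> None:
    """Write conformer sets as SDF V2000, one record per conformer; the
    record title is the ligand ID, so grouping survives a round trip."""
    Chem = _require_rdkit()
    writer = Chem.SDWriter(str(path))
    try:
        for cs in sets:
            for i, mol in enumerate(cs.mols):
                mol.SetProp("_Name", cs.ligand_id)
                mol.SetIntProp("conformer_index", i)
                writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> list[ConformerSet]:
    """Read SDF records and group conformers sharing a title into one
    :class:`ConformerSet` (first-seen title order)."""
    Chem = _require_rdkit()
    path = Path(path)
    if not path.exists():
        raise InputError(f"SDF not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    grouped: dict[str, list] = {}
    order: list[str] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise InputError(f"{path}: malformed SDF record at index {idx}")
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record_{idx}"
        if title not in grouped:
            grouped[title] = []
            order.append(title)
        grouped[title].append(mol)
    if not order:
        raise InputError(f"{path}: no SDF records")
    return [ConformerSet(ligand_id=t, mols=grouped[t]) for t in order]
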