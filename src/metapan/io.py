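"""Plain-text I/O: FASTA genomes, gene-call tables, manifests, ANI matrices,
cluster/matrix TSVs, annotation tables and module definitions.

Every artifact the pipeline writes is readable by the corresponding loader
(round-trip property); no binary databases are used.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import AniResult, GenomeRecord
from .enrichment import ModuleDefinition
from .pangenome import GeneCall
from .profiler import ORAL_SITES, SampleRecord

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description=genome.genome_id)
        for cid, seq in genome.contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path, genome_id: str, **meta) -> GenomeRecord:
    contigs = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    )
    return GenomeRecord(genome_id=genome_id, contigs=contigs, **meta)


def write_manifest(genomes: Sequence[GenomeRecord], path: str | Path) -> None:
    rows = [
        {
            "genome_id": g.genome_id,
            "species": g.species_label,
            "host": g.host,
            "oral": str(g.oral).lower(),
            "completeness": g.completeness,
            "contamination": g.contamination,
            "duplicate_of": g.duplicate_of or "",
        }
        for g in genomes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {
        "genome_id", "species", "host", "oral",
        "completeness", "contamination", "duplicate_of",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def manifest_record(row: Mapping[str, str], contigs) -> GenomeRecord:
    return GenomeRecord(
        genome_id=row["genome_id"],
        contigs=contigs,
        species_label=row["species"] or "unassigned",
        host=row["host"],
        oral=_BOOL.get(str(row["oral"]).lower(), False),
        completeness=float(row["completeness"]),
        contamination=float(row["contamination"]),
        duplicate_of=row["duplicate_of"] or None,
    )


def write_gene_calls(genes: Sequence[GeneCall], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "genome_id": g.genome_id,
            "contig_id": g.contig_id,
            "start": g.start,
            "stop": g.stop,
            "strand": g.strand,
            "protein": g.protein,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_calls(path: str | Path) -> List[GeneCall]:
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "stop": int})
    return [GeneCall(**row) for row in df.to_dict("records")]


def write_protein_fasta(genes: Sequence[GeneCall], path: str | Path) -> None:
    """Protein FASTA with headers genome_id|gene_id."""
    records = [
        SeqRecord(Seq(g.protein), id=f"{g.genome_id}|{g.gene_id}", description="")
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def write_ani_matrix(
    genome_ids: Sequence[str],
    ani: Mapping[Tuple[str, str], AniResult | float],
    path: str | Path,
) -> None:
    def val(a: str, b: str) -> float:
        if a == b:
            return 1.0
        r = ani.get((a, b)) or ani.get((b, a))
        return r.ani if isinstance(r, AniResult) else float(r)

    df = pd.DataFrame(
        [[val(a, b) for b in genome_ids] for a in genome_ids],
        index=genome_ids,
        columns=genome_ids,
    )
    df.to_csv(path, sep="\t")


def read_ani_matrix(path: str | Path) -> Dict[Tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    out: Dict[Tuple[str, str], float] = {}
    for a in df.index:
        for b in df.columns:
            if a != b:
                out[(a, b)] = float(df.loc[a, b])
    return out


def write_cluster_membership(clusters, path: str | Path) -> None:
    rows = []
    for c in clusters:
        for gid in c.members:
            rows.append({"cluster_id": c.cluster_id, "gene_id": gid,
                         "category": c.category})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_manifest(path: str | Path) -> List[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "oral_site", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample manifest missing columns: {sorted(missing)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
    records = []
    for row in df.to_dict("records"):
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                oral_site=row["oral_site"],
                total_reads=int(row["total_reads"]),
                mapped_reads=int(row.get("mapped_reads") or 0),
            )
        )
    return records


def write_modules(modules: Sequence[ModuleDefinition], path: str | Path) -> None:
    payload = [
        {
            "module_id": m.module_id,
            "name": m.name,
            "steps": [sorted(s) for s in m.steps],
        }
        for m in modules
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_modules(path: str | Path) -> List[ModuleDefinition]:
    payload = json.loads(Path(path).read_text())
    return [
        ModuleDefinition(
            m["module_id"], m["name"], tuple(frozenset(s) for s in m["steps"])
        )
        for m in payload
    ]


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "gene_id", "source", "accession"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if (df["accession"].fillna("") == "").any():
        raise ValueError("annotation table contains empty accessions")
    return df


def read_group_map(path: str | Path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["genome_id"], df["group"]))
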