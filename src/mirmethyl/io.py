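"""Reading and writing the pipeline's plain-text formats.

Beta matrices, annotation, metadata and ground truth travel as TSV;
MethyLight plates as CSV (sample_id, reaction, replicate, ct,
is_reference); sequences as FASTA via Biopython.
"""

from __future__ import annotations

import os
from importlib import resources

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import MatureMiRNA, load_annotation
from .diffmeth import MethylationDataset
from .quant import MethyLightPlate
from .simulate import GroundTruth


def write_methylation_dataset(dataset: MethylationDataset, outdir) -> dict[str, str]:
    """Write beta.tsv / annotation.tsv / metadata.tsv into ``outdir``; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "beta": os.path.join(outdir, "beta.tsv"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
    }
    dataset.beta.rename_axis("probe_id").to_csv(paths["beta"], sep="\t")
    if dataset.annotation is not None:
        dataset.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    dataset.metadata.rename_axis("sample_id").to_csv(paths["metadata"], sep="\t")
    return paths


def read_methylation_dataset(beta_path, metadata_path, annotation_path=None) -> MethylationDataset:
    beta = pd.read_csv(beta_path, sep="\t", index_col="probe_id")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    annotation = load_annotation(annotation_path) if annotation_path else None
    return MethylationDataset(beta=beta, metadata=metadata, annotation=annotation)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.rename_axis("probe_id").to_csv(path, sep="\t")


def read_ground_truth(path) -> GroundTruth:
    table = pd.read_csv(path, sep="\t", index_col="probe_id", keep_default_na=False)
    table["true_delta"] = table["true_delta"].astype(float)
    star_candidates = table.loc[(table["label"] == "hyper") & (table["mirna_gene"] != "none")]
    star = None
    if len(star_candidates):
        star = star_candidates.loc[star_candidates["true_delta"].idxmax(), "mirna_gene"]
    return GroundTruth(table=table, star_gene=star)


def write_plate_csv(plate: MethyLightPlate, path) -> None:
    wells = plate.wells.copy()
    if "is_reference" not in wells.columns:
        wells["is_reference"] = wells["sample_id"] == plate.reference_sample_id
    wells.to_csv(path, index=False)


def read_plate_csv(path, reference_sample_id: str | None = None, gene: str = "GENE") -> MethyLightPlate:
    wells = pd.read_csv(path)
    if reference_sample_id is None:
        if "is_reference" not in wells.columns:
            raise ValueError("plate CSV lacks is_reference; pass reference_sample_id explicitly")
        refs = sorted(set(wells.loc[wells["is_reference"].astype(bool), "sample_id"]))
        if len(refs) != 1:
            raise ValueError(f"expected exactly one reference sample, found {refs}")
        reference_sample_id = refs[0]
    return MethyLightPlate(wells=wells, reference_sample_id=reference_sample_id, gene=gene)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def load_mature_mirnas(path=None) -> dict[str, MatureMiRNA]:
    """Mature miRNA sequences keyed by mature name.

    With no path, loads the packaged fixture (the miR-199 family guides,
    miR-199b-5p and miR-199a-5p).  FASTA descriptions may carry a
    ``gene=...`` token naming the miRNA gene.
    """
    if path is None:
        ctx = resources.as_file(resources.files("mirmethyl.data").joinpath("mature_mirnas.fa"))
        with ctx as p:
            return load_mature_mirnas(p)
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        name = rec.id.removeprefix("hsa-")
        out[name] = MatureMiRNA(name=name, gene=gene, sequence=str(rec.seq))
    return out
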