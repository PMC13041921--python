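"""Standard-format readers and writers shared by all stages.

FASTA via Biopython (60-column wrap), BED/BEDPE/TSV via plain text and
pandas, trees as Newick. All coordinates are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .synthetic import SyntheticTruth, TruthRecord

_LAYER_RGB = {"active": "214,39,40", "inactive": "127,127,127"}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    try:
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    except FileNotFoundError as exc:
        raise InputError(f"FASTA not found: {path}") from exc


def write_truth_bed(truth: SyntheticTruth, path: str | Path) -> None:
    """BED9: name = feature_class, score 0, itemRgb unused; attributes packed
    into the name after a '|' when present."""
    truth.sort()
    with open(path, "w") as fh:
        for r in truth.records:
            name = r.feature_class
            if r.attributes:
                packed = ";".join(f"{k}={v}" for k, v in r.attributes)
                name = f"{name}|{packed}"
            fh.write(
                f"{r.sequence_name}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}"
                f"\t{r.start}\t{r.end}\t0,0,0\n"
            )


def read_truth_bed(path: str | Path) -> SyntheticTruth:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise InputError(f"{path}: expected >= 6 BED columns")
            name = parts[3]
            attrs: tuple[tuple[str, str], ...] = ()
            if "|" in name:
                name, packed = name.split("|", 1)
                attrs = tuple(
                    tuple(kv.split("=", 1)) for kv in packed.split(";") if "=" in kv
                )
            records.append(
                TruthRecord(parts[0], int(parts[1]), int(parts[2]), name, parts[5], attrs)
            )
    truth = SyntheticTruth(records)
    truth.sort()
    return truth


def write_track(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False,
              float_format="%.6g")


def read_track(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "bin_start", "value"]
    )
    return df


def write_annotations_bed(annotations, path: str | Path) -> None:
    """Satellite array annotations as BED9; family in the name field, layer
    encoded in itemRgb (active red, inactive gray)."""
    with open(path, "w") as fh:
        for a in sorted(annotations, key=lambda a: (a.sequence_name, a.start)):
            rgb = _LAYER_RGB.get(a.layer, "0,0,0")
            fh.write(
                f"{a.sequence_name}\t{a.start}\t{a.end}\t{a.family}\t"
                f"{a.n_monomers}\t+\t{a.start}\t{a.end}\t{rgb}\n"
            )


def write_monomers_bed(assignments, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in assignments:
            fh.write(
                f"{a.sequence_name}\t{a.start}\t{a.end}\t{a.family}\t"
                f"{a.score:.2f}\t{a.strand}\n"
            )


def write_spectrum_tsv(spectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("period\tscore\n")
        for period in sorted(spectrum.score_per_period):
            fh.write(f"{period}\t{spectrum.score_per_period[period]}\n")


def write_phrs_bedpe(phrs, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in phrs:
            fh.write(
                f"{s.seq_a}\t{s.start_a}\t{s.end_a}\t{s.seq_b}\t{s.start_b}\t"
                f"{s.end_b}\tphr\t{s.identity:.4f}\t+\t{s.orientation}\n"
            )


def write_network_tsv(network, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("a\tb\tshared_bp\tmean_identity\n")
        for a, b, bp, ident in network.edges:
            fh.write(f"{a}\t{b}\t{bp}\t{ident:.4f}\n")


def write_newick(tree, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_signatures(signatures, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            for km in sorted(sig.kmers):
                fh.write(f"{sig.sequence_name}\t{km}\n")
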