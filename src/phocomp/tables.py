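"""Published summary-table arithmetic for the two phosphorylase families.

The packaged table ``data/pho_lengths.tsv`` transcribes the printed cDNA /
CDS / gene / protein length columns (with percent identity to the rice
reference) for the twelve study species.  The functions here derive the
quantities those tables imply: total intron content (gene minus cDNA) and
protein length from the CDS (CDS/3 - 1 for a complete CDS with its stop
codon), and flag rows whose printed numbers are internally inconsistent
rather than silently correcting them.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .genestruct import total_intron_bp


def load_length_table() -> pd.DataFrame:
    """The packaged per-species length/identity table (both families)."""
    text = (resources.files("phocomp") / "data" / "pho_lengths.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    return df


def protein_len_from_cds(cds_bp: int) -> int:
    """Residue count of the protein encoded by a complete stop-terminated CDS."""
    if cds_bp % 3 != 0:
        raise ValueError(f"CDS length {cds_bp} is not a multiple of 3")
    return cds_bp // 3 - 1


def summarize(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Derived columns plus consistency flags for a length table.

    Adds ``intron_total_bp`` (gene - cDNA), ``protein_expected_aa``
    (CDS/3 - 1 where the CDS length is a clean multiple of 3) and
    ``flagged`` with the reason a row's printed values cannot all be right:
    a cDNA equal to the gene despite annotated introns, a CDS length off
    the codon grid, or a protein length disagreeing with its CDS.
    """
    if df is None:
        df = load_length_table()
    df = df.copy()
    intron_total = []
    expected_aa = []
    flags = []
    for _, row in df.iterrows():
        flag = []
        try:
            it = total_intron_bp(int(row.gene_bp), int(row.cdna_bp))
        except ValueError:
            it = None
            flag.append("gene_shorter_than_cdna")
        intron_total.append(it)
        if row.cds_bp % 3 == 0:
            aa = protein_len_from_cds(int(row.cds_bp))
            expected_aa.append(aa)
            if aa != row.protein_aa:
                flag.append("protein_cds_mismatch")
        else:
            expected_aa.append(None)
            flag.append("cds_not_codon_multiple")
        if it == 0:
            flag.append("no_intron_content")
        flags.append(";".join(flag))
    df["intron_total_bp"] = intron_total
    df["protein_expected_aa"] = expected_aa
    df["flagged"] = flags
    return df


def intron_total_range(df: pd.DataFrame, family: str) -> tuple[int, int]:
    """(min, max) total intron bp over a family's consistent rows.

    Rows with any consistency flag are excluded: a record whose printed
    cDNA equals its gene length while claiming several introns cannot
    contribute a meaningful intron total.
    """
    sub = df[(df.family == family) & (df.flagged == "")]
    vals = sub.intron_total_bp.astype(int)
    return int(vals.min()), int(vals.max())
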