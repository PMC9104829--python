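"""Optional network helper: fetch protein records by accession.

Everything else in the package runs fully offline; this module exists so a
user with network access can pull the published protein records (e.g.
NP_001296783.1) and confirm their lengths against the packaged length
table.  It is never exercised by the test suite.
"""

from __future__ import annotations

from io import StringIO
from urllib.request import urlopen

from Bio import SeqIO

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=protein&rettype=fasta&retmode=text&id={acc}")


def parse_protein_fasta(text: str) -> dict[str, int]:
    """Accession -> protein length for a FASTA payload."""
    out = {}
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        out[rec.id] = len(rec.seq)
    return out


def fetch_protein_lengths(accessions: list[str], timeout: float = 30.0) -> dict[str, int]:
    """Fetch protein lengths from NCBI efetch (requires network access)."""
    url = EFETCH.format(acc=",".join(accessions))
    with urlopen(url, timeout=timeout) as fh:
        text = fh.read().decode()
    return parse_protein_fasta(text)
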