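"""Download the three DENV-3 genomes used by the genomic application tests.

Fetches GenBank records OQ706226, OQ706227 and OQ706228 from NCBI efetch and
writes one FASTA per accession under data/.  Requires network access; run
once, then `pytest tests/test_acceptance.py::test_dengue_genome_application`
or `pmm fit data/OQ706226.fasta --order 3 --penalty loglog_n`.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

ACCESSIONS = ("OQ706226", "OQ706227", "OQ706228")
URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


def main() -> None:
    out_dir = Path(__file__).resolve().parent.parent / "data"
    out_dir.mkdir(exist_ok=True)
    for acc in ACCESSIONS:
        text = urllib.request.urlopen(URL.format(acc=acc), timeout=60).read().decode()
        if not text.startswith(">"):
            raise RuntimeError(f"unexpected efetch response for {acc}")
        path = out_dir / f"{acc}.fasta"
        path.write_text(text)
        n = sum(len(line.strip()) for line in text.splitlines() if not line.startswith(">"))
        print(f"{acc}: {n} nt -> {path}")


if __name__ == "__main__":
    main()
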