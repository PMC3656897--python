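"""Fetch the xantholysin gene-cluster accessions into data/real/.

Downloads the GenBank flat files KC297505 (xtlFRA region) and KC297506
(xtlBCDE region) from NCBI E-utilities.  Network access required; nothing in
the test suite depends on having run this, but the real-sequence
reproduction checks activate once the files are present.

    python scripts/fetch_accessions.py
"""

import pathlib
import urllib.request

ACCESSIONS = ["KC297505", "KC297506"]
URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text"
)
OUT = pathlib.Path(__file__).resolve().parents[1] / "data" / "real"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = OUT / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present")
            continue
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(URL.format(acc=acc), timeout=60) as r:
            dest.write_bytes(r.read())
        print(f"wrote {dest}")


if __name__ == "__main__":
    main()
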