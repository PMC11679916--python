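"""Packaged digitized reference-cohort tables.

Three fixtures ship with the package, digitized from the published summary
tables of a 104-trio consanguineous ASD cohort:

* ``cohort_snv`` — one row per printed SNV/indel (134 rows), with a curated
  ``is_candidate`` flag reproducing the published final candidate set
  (90 variants, 83 genes);
* ``cohort_cnv`` — the ten de novo micro-CNVs called in eight probands;
* ``clinical``  — cohort-level clinical counts and percentages.

The files are bit-controlled: the loader verifies a SHA-256 checksum and a
column schema before returning anything, so silent edits fail loudly.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

_SCHEMAS = {
    "cohort_snv": [
        "subject_id", "sex", "consanguinity", "gene", "accession", "chrom",
        "hgvs_c", "hgvs_p", "variant_type", "inheritance", "gnomad_af",
        "gnomad_af_note", "qgp_af", "cadd", "acmg", "mis_z", "pli",
        "known_novel", "is_candidate",
    ],
    "cohort_cnv": [
        "subject_id", "sex", "chrom", "start", "end", "cnv_type",
        "printed_size", "cytoband", "genes", "location", "inheritance",
    ],
    "clinical": ["key", "value", "unit"],
}

# SHA-256 of the packaged files; regenerated only when a fixture is
# deliberately re-digitized.
_CHECKSUMS = {
    "cohort_snv": "8d2fa92165089b2eae044e8f2fc04450549263843e8b207c25509185a2daff3b",
    "cohort_cnv": "484bcfb88c667a14c4de69f326a6f6a4dfd4ee2726e2675081312373552aa000",
    "clinical": "95a375c0977a935a5ca98794bd731378045afb7b2a9c66bbe8a4bdcab3aa6f10",
}

_NUMERIC = {
    "cohort_snv": ["subject_id", "gnomad_af", "qgp_af", "cadd", "mis_z", "pli", "is_candidate"],
    "cohort_cnv": ["subject_id", "start", "end"],
    "clinical": ["value"],
}


def _fixture_bytes(name: str) -> bytes:
    ref = resources.files("trioscope.data").joinpath(f"{name}.tsv")
    return ref.read_bytes()


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by name (cohort_snv, cohort_cnv, clinical)."""
    if name not in _SCHEMAS:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_SCHEMAS)}")
    raw = _fixture_bytes(name)
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValueError(
            f"fixture {name!r} failed its checksum (got {digest}); "
            "the packaged file has been modified"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", comment="#", dtype=str)
    if list(df.columns) != _SCHEMAS[name]:
        raise ValueError(f"fixture {name!r} schema mismatch: {list(df.columns)}")
    for col in _NUMERIC[name]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def candidate_rows(snv: pd.DataFrame | None = None) -> pd.DataFrame:
    """The curated final-candidate subset of the SNV fixture."""
    if snv is None:
        snv = load_fixture_table("cohort_snv")
    return snv[snv["is_candidate"] == 1].copy()


def clinical_value(key: str) -> float:
    df = load_fixture_table("clinical")
    hit = df[df["key"] == key]
    if hit.empty:
        raise KeyError(f"no clinical fixture entry {key!r}")
    return float(hit["value"].iloc[0])
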