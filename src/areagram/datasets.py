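"""Bundled example data: the *Tropidurus* case study.

Three transcribed presence/absence matrices for the 23 recognised
*Tropidurus* species over South American operational geographic units,
plus the species cladogram used for BPA coding:

* ``load_quadrat_matrix`` — 50 occupied 5x5-degree quadrats (+ outgroup)
  x 23 species;
* ``load_province_matrix`` — 20 biogeographic provinces (+ outgroup)
  x 23 species;
* ``load_bpa_matrix`` — the province matrix for the 20 species present in
  the phylogenetic hypothesis, expanded with 19 hypothetical-ancestor
  columns by additive binary coding;
* ``load_taxon_cladogram`` — a cladogram of those 20 species consistent
  with the ancestor columns (derived from, and validated against, the
  coded matrix; where identical ancestor columns admit more than one
  resolution this is one of them).

``fixture_checksums`` returns sha256 digests of the shipped files.
"""
from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .bpa import TaxonCladogram
from .matrix import PresenceMatrix

__all__ = [
    "load_quadrat_matrix",
    "load_province_matrix",
    "load_bpa_matrix",
    "load_taxon_cladogram",
    "fixture_checksums",
]

_FILES = {
    "quadrats": "quadrats_23species.csv",
    "provinces": "provinces_23species.csv",
    "bpa": "bpa_provinces_39chars.csv",
    "cladogram": "taxon_cladogram_bpa.nwk",
}


def _data_path(name: str):
    return resources.files("areagram.data").joinpath(name)


def _load_csv(name: str) -> PresenceMatrix:
    with resources.as_file(_data_path(name)) as p:
        df = pd.read_csv(p, index_col=0)
    return PresenceMatrix(df, outgroup="Outgroup")


def load_quadrat_matrix() -> PresenceMatrix:
    return _load_csv(_FILES["quadrats"])


def load_province_matrix() -> PresenceMatrix:
    return _load_csv(_FILES["provinces"])


def load_bpa_matrix() -> PresenceMatrix:
    return _load_csv(_FILES["bpa"])


def load_taxon_cladogram() -> TaxonCladogram:
    nwk = _data_path(_FILES["cladogram"]).read_text().strip()
    return TaxonCladogram.from_newick(nwk)


def fixture_checksums() -> dict[str, str]:
    out = {}
    for key, name in _FILES.items():
        out[name] = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
    return out
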