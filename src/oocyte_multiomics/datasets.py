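"""Packaged fixture tables.

Two small raw-abundance matrices ship with the package: subcortical maternal
complex (SCMC) proteins and selected epigenetic modifier proteins, each
measured in 4 WT, 3 Het and 4 Hom bulk GV-oocyte samples from an *Nlrp5*
knockout line, plus the sample->genotype design.
"""

from importlib import resources

import pandas as pd

from .proteomics import AbundanceMatrix

__all__ = ["load_design", "load_scmc_abundance", "load_epimod_abundance"]

_DATA = resources.files(__name__.rsplit(".", 1)[0]) / "data"


def load_design() -> pd.Series:
    with resources.as_file(_DATA / "genotype_design.tsv") as p:
        return pd.read_csv(p, sep="\t", index_col=0)["group"]


def _load(name: str) -> AbundanceMatrix:
    with resources.as_file(_DATA / name) as p:
        values = pd.read_csv(p, sep="\t", index_col=0).astype(float)
    return AbundanceMatrix(values=values, design=load_design())


def load_scmc_abundance() -> AbundanceMatrix:
    """Raw intensities for 16 known/putative SCMC proteins."""
    return _load("scmc_abundance.tsv")


def load_epimod_abundance() -> AbundanceMatrix:
    """Raw intensities for 11 epigenetic modifier proteins."""
    return _load("epimod_abundance.tsv")
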