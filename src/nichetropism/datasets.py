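"""Accessors for the bundled study fixtures.

The fixtures transcribe the published nine-pair hub-tropism survey: the
*Wolbachia* strain phylogeny, the host (line-level) phylogeny, and the
per-pair tropism frequencies.  See ``data/README.md`` for provenance and for
which two frequency values are band-constrained stand-ins.
"""

from __future__ import annotations

from importlib import resources

import dendropy
import pandas as pd

from .phylosignal import bin_frequency, load_tree

__all__ = [
    "load_wolbachia_tree",
    "load_drosophila_tree",
    "load_tropism_frequencies",
    "wolbachia_character",
    "drosophila_character",
]


def _data_path(name: str):
    return resources.files("nichetropism.data").joinpath(name)


def load_wolbachia_tree() -> dendropy.Tree:
    """Nine-strain *Wolbachia* phylogeny (supergroups A and B)."""
    with resources.as_file(_data_path("wolbachia_tree.nwk")) as p:
        return load_tree(p)


def load_drosophila_tree() -> dendropy.Tree:
    """Host phylogeny: one leaf per surveyed *Drosophila* species.

    The *simulans* complex is kept as a soft trichotomy; its internal
    resolution does not change the tropism character's tree length.
    """
    with resources.as_file(_data_path("drosophila_tree.nwk")) as p:
        return load_tree(p)


def load_tropism_frequencies() -> pd.DataFrame:
    """Per-pair hub-tropism frequencies (percent) for the nine survey pairs."""
    with resources.as_file(_data_path("tropism_frequencies.csv")) as p:
        return pd.read_csv(p)


def wolbachia_character() -> dict[str, str]:
    """Binned three-state tropism character keyed by *Wolbachia* strain."""
    df = load_tropism_frequencies()
    return {
        row.strain: bin_frequency(row.frequency_percent) for row in df.itertuples()
    }


def drosophila_character() -> dict[str, str]:
    """Binned three-state tropism character keyed by host species.

    A species surveyed with more than one *Wolbachia* strain (D. simulans:
    wRi and wNo) is scored by its highest observed tropism frequency — the
    species displays hub tropism if any of its surveyed infections does.
    """
    df = load_tropism_frequencies()
    best = df.groupby("host")["frequency_percent"].max()
    return {host: bin_frequency(freq) for host, freq in best.items()}
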