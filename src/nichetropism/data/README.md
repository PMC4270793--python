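# Bundled study fixtures

These files transcribe the published survey of *Wolbachia* hub tropism across
nine *Drosophila* host line / *Wolbachia* strain pairs, for use by the
phylogenetic-signal analysis.  They are **transcriptions, not deposited
data** — the original figures print the trees graphically and no machine-
readable topology or full frequency table accompanies the text — so they
carry the following caveats:

* `wolbachia_tree.nwk` — nine-strain *Wolbachia* topology.  Supergroup A
  (wMel with the yakuba-complex strains wYak/wTei; the wRi-like pair
  wRi/wAna; wWil and wSh) and supergroup B (wNo, wMau) follow published
  multilocus phylogenies of these strains.  Branch lengths are not recorded;
  the parsimony analysis does not use them.
* `drosophila_tree.nwk` — host species phylogeny, one leaf per surveyed
  *Drosophila* species (eight: *D. simulans* was surveyed with two strains
  but is one species).  The *simulans* complex is a soft trichotomy; every
  binary resolution of it yields the same tree length for the tropism
  character.  A species with two surveyed infections is scored by its
  highest observed tropism frequency.
* `tropism_frequencies.csv` — hub-tropism frequency (percent of hubs with a
  hub/surrounding density ratio >= 1.5) per pair.  The values for wAna (95),
  wMel (71), wMau (71), wRi (17), wTei (2.3), wSh (0) and wNo (0) are printed
  in the survey's text.  wYak and wWil are reported only as "moderate"
  (10-59%); the 30 and 40 here are synthetic stand-ins inside that band, and
  every analysis in this package that consumes them depends only on the band,
  not the exact value.

Users may substitute their own newick trees and trait tables; see
`nichetropism.datasets` for the loading API.
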