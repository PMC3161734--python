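# chlamyflux

Elementary-flux-mode analysis of circadian metabolic regulation in the green
alga *Chlamydomonas reinhardtii*.

At night, the RNA-binding factor CHLAMY1 binds perfect (UG)₇ dinucleotide
repeats in the 3′ UTRs of specific mRNAs and represses their translation.
Several of the affected enzymes sit in nitrogen assimilation and amino-acid
biosynthesis. This package asks what that repression does to the metabolic
state: it enumerates every elementary flux mode (EFM) of a stoichiometric
network of night-time nitrogen metabolism, scores each mode by a carbon
yield, flags the modes that use a CHLAMY1-controlled enzyme, and quantifies
how complete or partial downregulation shifts the yield distribution. It is
written for systems biologists who want constraint-based pathway analysis
coupled to sequence-level regulatory evidence.

## Model and statistics

An EFM is a flux vector `v` with `S·v = 0` over the internal metabolites
(`S` the stoichiometric matrix), non-negative flux through irreversible
reactions, and minimal support — the indivisible routes of the network.
Enumeration uses the double description method on the split (irreversible)
flux cone with exact integer arithmetic and a combinatorial adjacency test;
a brute-force support-subset enumerator serves as an independent oracle in
the tests.

For a mode that converts the night-time carbon sources (glucose-6-phosphate
from starch breakdown, and acetate) into a target amino acid, the carbon
yield is

    Y = (n_AA · c_AA) / Σ_s (n_s · c_s)

with `n` the net molar coefficients of the mode's overall equation and `c`
the carbon counts; CO₂ is external but never counted as a source, so Y > 1
signals net non-photosynthetic CO₂ fixation. Downregulation is modelled two
ways: *knockout* discards every mode using a regulated enzyme, and the
*weighted* scheme keeps affected modes with weight `w_a` (default 1/10,
i.e. residual activity of 10%), using the weighted mean
`Ȳ_w = Σ w_i Y_i / Σ w_i` and weighted empirical-CDF quantiles (exactly the
10×/1× replicated boxplot for `w_a = 1/10`).

The packaged network is a curated ~40-reaction core model of *C.
reinhardtii* night-time metabolism (glycolysis, oxidative pentose phosphate
pathway, acetate activation, citrate cycle with glyoxylate shunt,
nitrate/nitrite/ammonium assimilation, and biosynthesis of Gly, Ala, Asn,
Lys, Arg, with energy and redox carriers internal). Six enzymes are marked
CHLAMY1-regulated — glucose-6-phosphate isomerase, NADP-dependent
isocitrate dehydrogenase, nitrite reductase, argininosuccinate lyase,
pyruvate kinase and the pyruvate dehydrogenase complex (see
`docs/methods.md` for the curation rationale). The shipped 3′-UTR FASTA is
a synthetic stand-in with the motif planted in the regulated genes, so the
whole sequence→regulation→flux path runs self-contained.

## Worked example

```sh
python analysis/02_enumerate_modes.py
python analysis/04_yield_distributions.py
```

prints (abridged):

```
3771 elementary flux modes in 5.5s
  Gly: 1274 modes, 1250 affected (98.12%), 24 survive knockout
  ...
  Arg: 1347 modes, 1347 affected (100.00%), 0 survive knockout
  overall: 55/3771 modes (1.46%) survive complete knockout

target   scheme  n_modes   mean  weighted_mean    max
   Asn      all      556 0.4904         0.4904 1.2083
   Asn knockout        8 0.8032         0.8032 1.1111
   Asn weighted      556 0.4904         0.5263 1.2083
knockout: mean yield increases for 4/4 amino acids; maximum never increases: True
weighted: mean yield increases for 4/4 amino acids; maximum never increases: True
arginine under complete knockout: 0 modes (argininosuccinate lyase is essential)
```

Read: over 96% of all biosynthetic routes use at least one regulated
enzyme, and the repressed routes are predominantly the low-yield ones —
removing or down-weighting them *raises* the mean carbon yield of every
amino acid while the maximum yield never rises, and arginine synthesis
(and all nitrate/nitrite use) becomes impossible because ASL and NiR are
essential. That is the physiological picture of CHLAMY1 as a night-time
energy-conservation switch. The other drivers validate the model
(`01`), derive the regulated set from UTR scans (`03`), run the
GAP-variant and ASL/NiR-only scenarios plus a weight sweep (`05`), and
profile amino-acid composition (`06`); tables land in `results/`.

A CLI wraps the same functions: `chlamyflux model validate`,
`chlamyflux efm enumerate`, `chlamyflux scan utr`, `chlamyflux scenario run
--name full --outdir out`, `chlamyflux simulate network`, ...

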