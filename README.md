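# nqbridge

Descriptor and trajectory analyses for substituent effects in
1,4-naphthoquinone derivatives — the quinones whose hydroxy-substituted
members (8-hydroxy-1,4-naphthoquinone, naphthazarin) carry one or two
intramolecular O–H...O hydrogen bridges. The package is aimed at
computational chemists post-processing static DFT results (geometries,
bond-length tables, partial charges, relaxed proton scans) and
molecular-dynamics trajectories of such systems.

It implements, as one tested pipeline:

* **HOMA** — the Harmonic Oscillator Model of Aromaticity,
  `HOMA = 1 − (α/n) Σ (d_opt − dᵢ)²` with α = 257.7, d_opt = 1.388 Å,
  from geometries or published bond-length tables;
* **cSAR** — the charge of the Substituent Active Region,
  `cSAR(X) = q(X) + q(C_ipso)`, from per-atom partial-charge tables;
* **PT profiles** — barrier height and second-minimum energy of 1-D
  relaxed proton-transfer scans;
* **bridge dynamics** — donor/acceptor distance series, proton
  possession fractions, hysteresis-filtered transfer events and
  inter-bridge synchrony for twin-bridge trajectories;
* **velocity power spectra** — Wiener–Khinchin vibrational densities of
  states and ν(OH) band barycenters per bridge proton;
* **a synthetic coupled-bridge generator** — a 4-state Markov-switching
  model with analytic ground truth (stationary possession, concordance,
  injected stretch frequency) standing in for unavailable ab initio MD;
* **series reports** — per-compound descriptor tables with Spearman
  rank correlations across a substitution series.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

HOMA of the benzene ring (ring II) of the parent compounds, from the
packaged DFT bond-length table:

```bash
nqbridge homa --bonds src/nqbridge/data/parent_bond_lengths.tsv \
    --labels "C10-C5,C5-C6,C6-C7,C7-C8,C8-C9,C9-C10"
```

prints

```
1a_xray	0.9842
1a_dft	0.9955
2a_xray	0.8336
2a_dft	0.9524
3a_xray	0.5240
3a_dft	0.8782
```

Reading: the unsubstituted benzene ring of 1,4-naphthoquinone (1a) is
essentially fully aromatic (0.99); one intramolecular hydrogen bridge
(2a) lowers it to ~0.95, and the twin bridges of naphthazarin (3a) to
~0.88 — bond-length equalization degrades as the chelate quasi-rings
polarize the ring. (X-ray columns are noisier than DFT ones; the 3a
X-ray value reflects the disorder in that crystal structure.)

A synthetic twin-bridge trajectory and its dynamics:

```bash
nqbridge synth --kfwd 0.8 --krev 1.6 --gamma 3 --duration 25 \
    --seed 42 --out traj.xyz --truth truth.yaml
cat > bridges.yaml <<EOF
compound: synthetic
bridges:
  O1-H1-O3: {donor: 1, proton: 3, acceptor: 2}
  O2-H2-O4: {donor: 4, proton: 6, acceptor: 5}
EOF
nqbridge dynamics --xyz traj.xyz --config bridges.yaml
```

prints

```
bridge	donor_percent	acceptor_percent	n_frames
O1-H1-O3	70.0	30.0	17218
O2-H2-O4	69.1	30.9	17218
events	20	15
match_fraction	0.450
max_delay_fs	450.1
```

The analytic stationary donor fraction for these rates (`truth.yaml`)
is 0.776 per bridge; this 25 ps run sits within sampling error of it
(about 35 sojourns), and the near-equality of the two bridges reflects
the coupling (γ = 3, concordance probability 0.92). The ν(OH)
barycenter of a bridge proton:

```bash
nqbridge spectrum --xyz traj.xyz --atoms 3 --window 2200:3400
# barycenter_cm-1  2750.5
# resolution_cm-1  5.61
```

recovering the injected 2750 cm⁻¹ stretch to within one bin.

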