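# sheetfold

Rule-based prediction of possible-but-unobserved ("novel") αβ-protein
folds from β-sheet topology, with blueprint compilation for de novo
design.

αβ-Proteins arrange an open β-sheet against α-helices, and most of the
fold diversity observed in nature belongs to this class.  Abstracting a
fold to its **β-sheet topology** — the order in which the
sequence-numbered strands appear across the sheet and the up/down
orientation of each — makes fold space finite and enumerable: an
n-stranded open sheet admits exactly

    n! × 2^(n−2)

symmetry-distinct topologies (strand permutations × orientation vectors,
identified under the three 180° rigid rotations of the sheet; mirror
images stay distinct because strand connections are chiral).  Only some
of these are *possible*: the chain segments linking sequence-consecutive
strands (β-X-β motifs) obey strong conformational preferences, and a
topology that forces two connections into conflict is *frustrated*.

`sheetfold` implements this program end to end for sheets of 3–8 strands:

* **topology** — parse/format (`1342:uddd`), canonicalize under sheet
  rotation, enumerate exhaustively;
* **rules** — classify every topology as frustration-free or frustrated
  under three rules: connection **jump distance** (parallel < 4,
  antiparallel < 2, with the Greek-key exemption for the antiparallel
  jump-2 motif and its circular permutants), connection **overlap** (two
  connections competing for the same face region, S-type, are
  disfavored) and connection **ending** (two parallel motifs ending on
  adjacent parallel strands must arrive from the same face);
* **observation** — score topologies against an ECOD-like
  Family/Homology domain table: occupation ratio
  `OR(i) = Σ_j R_Family(j) / N_Family` per Homology group, observation
  frequency `Σ_i OR(i)`, and the strict `< 1/4` unobserved threshold;
  predicted novel folds = frustration-free ∧ unobserved;
* **extraction** — recover a canonical topology from PDB coordinates via
  strand pairing graphs (hydrogen-bond or Cα-contact support, open
  unbranched sheets only);
* **blueprint** — compile a topology into a per-residue design blueprint
  (H/E/L secondary structure + ABEGO loop patterns from a fixed allowed
  table) and into idealized mock Cα coordinates with right-handed
  connector routing.

For four-stranded sheets the engine reproduces the reference split of
the 96 topologies into **43 frustration-free / 53 frustrated** (10/12
for three strands), including the worked cases: the meander
`1234:udud` is clean, `1342:uddd` violates the jump-distance and
overlap rules, and the knot-forming all-parallel `3142:uuuu` is
frustration-free.

## Worked example

Classify one topology and list what is wrong with it:

```text
$ sheetfold classify --topology 1342:uddd
topology        n       frustration_free        violations
1342:uddd       4       false   jump_distance(1);overlap(1,2);overlap(1,3)
```

Connection 1 (strand 1 → strand 2) is an antiparallel motif jumping two
intervening strands outside a Greek-key window — a jump-distance
violation — and its edge bend moreover collides with both crossover
connections that terminate beneath it (overlap violations involving
connection pairs 1,2 and 1,3).  No ending violation occurs.

Enumerate and classify everything at n = 4, then predict novel folds
against a synthetic observation table:

```text
$ sheetfold enumerate --strands 4 | tail -n +2 | wc -l
96
$ sheetfold classify --all 4 -o classes.tsv     # 43 true / 53 false
$ sheetfold fixtures --spec "1234:udud,1,2,1/2" -o table.tsv
$ sheetfold predict-novel -n 4 --table table.tsv | head -4
topology        frequency       status
1234:uddd       0       unobserved
1234:uddu       0       unobserved
1234:udud       0       unobserved
```

The fixture gives the meander one Homology group with two families at
match fractions 1 and 1/2, hence frequency 0.75 ≥ 1/4 → observed, so 42
of the 43 frustration-free topologies remain novel (with an empty table
it is all 43).

Compile a design blueprint and a mock structure for the knotted fold:

```sh
sheetfold blueprint -t 3142:uuuu -o nf8.blueprint   # 71 residues: 4 E-strands, 3 helices
sheetfold mock -t 3142:uuuu -o nf8_mock.pdb --strand-table nf8_strands.tsv
sheetfold extract nf8_mock.pdb --strands-tsv nf8_strands.tsv   # → 2413:uuuu (canonical form)
```

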