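# chemlike

Analysis of *chemistry-like* reaction networks. A reaction network (a
directed, integer-weighted hypergraph over species) is chemistry-like when
it is **thermodynamically sound** (no futile cycle of irreversible
reactions — no perpetuum mobile can be built) and **conservative** (a
strictly positive conservation law exists — no mass can be created or
destroyed). Both properties are decided exactly from the stoichiometric
matrix, with certificates for either outcome.

Features:

* reaction networks from equation files (`.rxn`) or labelled TSV matrices;
  classification of reactions (proper / import / export), proper part,
  composite and net reactions, complex-matrix factorization `S = Y Z`
* thermodynamics: Hess's law `g = Sᵀ G`, recovery of molecular energies,
  futile-cycle enumeration (extreme rays of `{v ≥ 0 : S v = 0}`), perpetuum
  mobile detection, lax and strict soundness decisions with exact witness /
  certificate pairs (theorems of the alternative), reversible completion
* conservation: exact integer left-kernel bases (conservation laws),
  conservativity with certificates (positive law vs. mass-creating flow),
  complete enumeration of minimal moiety conservation laws (Hilbert-basis
  style), the mm-representation, obligatory isomer classes, net
  isomerization flows, oligomer ratios
* realizations: sum-formula instances and realizations (atom matrices with
  `A S = 0`), infinitely many inequivalent realizations, Lewis-style
  vertex-colored multigraph realizations, and an injective construction
  that assigns pairwise non-isomorphic graphs even to obligatory isomers
* random generation of networks that are conservative and (strictly)
  thermodynamically sound *by construction*, plus catalyst augmentation and
  closure-respecting random subnetworks

All certificates are computed or verified in exact rational arithmetic
(`fractions` / sympy); floating point never decides anything.

## CLI

```sh
chemlike fixtures                       # list built-in example networks
chemlike check --fixture eq9            # full report; exit 2 = not chemistry-like
chemlike check --rxn mynet.rxn --json
chemlike check --matrix S.tsv --irreversible r3 --irreversible r6
chemlike kernel --fixture eq18          # conservation-law basis (TSV)
chemlike mcl --fixture eq23             # minimal moiety conservation laws
chemlike isomers --fixture eq27         # obligatory isomer classes
chemlike realize --fixture eq23         # sum formulas (add --injective for graphs)
chemlike random --seed 7 --strict       # emit a random chemistry-like network
```

Exit codes: `0` chemistry-like, `2` analyzed but not chemistry-like,
`1` runtime error, `64` usage error.

### Reaction file format

```
# one reaction per line; coefficients default to 1
r1: 2 A + B -> C
r2: A <=> B          # reversible; expanded into columns r2 and r2_rev
r3: 0 -> A           # import reaction (0 or ∅ denotes the empty side)
```

Matrix TSV: first row reaction ids, first column species ids, integer
cells; reversibility via `--irreversible` flags (default: all
irreversible).

## Library example

```python
from chemlike import parse_rxn, is_thermodynamically_sound, is_conservative

net = parse_rxn("r1: A + B -> C + D\nr2: C -> A + B\n")
S = net.stoichiometric_matrix()
print(is_thermodynamically_sound(S, net.irreversible_ids).sound)
cert = is_conservative(S)
print(cert.kind, cert.vector)
```
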