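# Full-size experiment configurations

These configurations reproduce the full-protein experiments (the 121-residue
lasso glycoprotein, PDB entry 2GMF, chain A) and need a user-supplied PDB
file plus substantial CPU time: one 2048-trajectory ensemble at
tau_run = 1.5e4 is of the order of 10^11 force evaluations.

## Preparation

    lassofold prepare --pdb 2gmf.pdb --chain A \
        --bridge 88:121 --bridge 54:96 \
        --out ref_2gmf.json --out-native native_2gmf.xyz

The lasso bridge is b1 = (88, 121); its covalent loop is threaded twice by
the 43–53 hairpin (an L2 lasso). Bridge b2 = (54, 96) carries no lasso.
The reduced-structure topology spec is `topo_2gmf.json` in this directory
(loop = cysteines 88/121 plus three roughly equidistant interior residues;
tail = the hairpin, split at its turn); verify L > 0.9 on the native
structure before production use, and enlarge the reduction (e.g. M_l = 9,
M_t = 5) for the floppier Go model.

## Homogeneous-model ensembles (folding probability and pathways)

2048 trajectories of tau_run = 1.5e4 at T = 0.1, each redox condition:

    for S in $(seq 0 2047); do
      lassofold simulate --model efm --ref ref_2gmf.json \
          --native native_2gmf.xyz --topo topo_2gmf.json \
          --temperature 0.1 --tau-run 15000 --seed $S \
          --redox reducing --out runs_red/run$S
    done
    lassofold analyze --runs runs_red/ --bridge-sigma 1.328 --out summary_red.json

(sigma_b1 = 1.992/1.5 = 1.328 for the native b1 distance; repeat with
`--redox oxidizing`.)

## Go-model ensembles

As above with `--model go` and `--temperature 0.7` (kinetically optimal) or
`--temperature 1.1` (backtracking regime). Contacts default to a 7.5 Å
Calpha cutoff; pass a SMOG-style contact list through the library API for
shadow-map contacts.

## Force-field optimization (MFFO)

30 cycles at the full-size defaults (N_K = 16, N_win = 6, N_low = 4,
m = 50, n = 16, tau_run = 3.5e3, oxidizing):

    lassofold optimize --ref ref_2gmf.json --native native_2gmf.xyz \
        --config mffo_full.yaml --cycles 30 --seed 1 \
        --temperature 0.1 --redox oxidizing \
        --out best_ff.json --history history.csv

Then re-test the optimized model over 2048 trajectories per condition with
`lassofold simulate --ff best_ff.json ...`.
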