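# rxnbarrier

Prediction of reaction barrier heights (activation energies, kcal/mol)
from atom-mapped reaction SMILES with a directed message-passing neural
network over the **condensed graph of reaction** (CGR), optionally
augmented with machine-learned quantum-mechanical descriptor columns and
with **3D positional descriptors** (AEV, SOAP) computed from reactant,
transition-state and product conformers.  It is aimed at computational
chemists who want barrier-height regression models that can exploit
transition-state geometry where it is available — including geometry
produced upstream by generative TS models — while degrading gracefully to
a purely 2D graph model where it is not.

## Model

A reaction is encoded as a single graph by superimposing the reactant and
product molecular graphs: each atom `v` carries the concatenation of its
per-side feature vectors `x_v = x_v^r ‖ x_v^p` (element, degree, formal
charge, hybridization, hydrogen count, aromaticity as one-hots; atomic
mass / 100), and each bond in the union of the two bond sets carries
`e_vw = e_vw^r ‖ e_vw^p` (bond order, conjugation, ring membership and
ring size), with the half for a side where the bond does not exist set to
zero — so bond formation and cleavage are explicit in the features.

Messages live on directed edges.  With `e_vw = cat(x_v, e_vw)`,

    h⁰_vw   = W_i · e_vw
    h^{t+1}_vw = τ( h⁰_vw + W_h · Σ_{k ∈ N(v)\{w}} h^t_kv ),  t = 0 … T−1
    h_v     = τ( W_0 · cat(x_v, Σ_k h^T_kv) )
    h_m     = pool_v h_v            (mean by default)
    ŷ       = FFN(h_m)              (kcal/mol, targets z-scored for training)

Auxiliary per-atom features — ml-QM descriptor columns (13 atom / 4 bond /
20 molecular = 37) or per-atom positional descriptors concatenated over
the requested roles (r, ts, p) — can be attached raw, or embedded by a
linear layer + ReLU, optionally followed by one self-attention pass over
the reaction's atoms, and joined either before message passing or after
it.  The AEV (Behler–Parrinello symmetry functions with smooth cosine
cutoff) and SOAP (Gaussian-density power spectrum) descriptors are
computed analytically and are exactly invariant to rigid motions; learned
foundation-model descriptors enter only through precomputed provider
tables.

Three dataset splitters are included: random 90/5/5, a reaction-core split
that keeps every bond-change pattern inside one partition, and a
barrier-height split that holds out the lowest and highest 5% of barriers.
Training follows a fixed protocol (AdamW, β₁ = 0.9, β₂ = 0.999, ε = 1e-8,
cosine annealing with 10 warmup steps, batch 50), and a permutation
feature importance report ranks auxiliary columns by the increase in MAE
when each is shuffled at prediction time.

## Worked example

The synthetic fixture generator produces hydrogen-transfer reactions
R1–H + R2 → R1 + H–R2 whose barrier is a known linear function of the
bond-change pattern plus `γ·d_TS`, where `d_TS` is the forming-bond
distance in the transition state — a geometric quantity invisible to any
2D graph model.

```python
from rxnbarrier.data import featurize_reactions
from rxnbarrier.descriptors3d import DescriptorConfig
from rxnbarrier.dmpnn import ModelConfig
from rxnbarrier.splits import random_split
from rxnbarrier.synthetic import FixtureConfig, generate
from rxnbarrier.train_eval import TrainConfig, evaluate, train

recs = generate(FixtureConfig(n_reactions=2000, seed=7))   # σ=0.5, γ=7 defaults
rxns = [r.reaction for r in recs]
split = random_split([r.id for r in rxns], seed=7)

model = ModelConfig(hidden_dim=64, depth=3, ffn_layers=2, ffn_hidden_dim=64)
tcfg = TrainConfig(epochs=30, batch_size=50, learning_rate=1e-3, seed=7)

ds = featurize_reactions(rxns)                             # graph only
s0, _ = train(ds.subset(split.train), ds.subset(split.validation), model, tcfg)
print("no coord :", evaluate(s0, ds.subset(split.test)).as_dict())

aev = DescriptorConfig(kind="aev", elements=("H", "C", "N", "O", "S"))
ds3 = featurize_reactions(rxns, conformers={r.reaction.id: r.conformers for r in recs},
                          roles_used=("ts",), descriptor_config=aev)
coord = ModelConfig(hidden_dim=64, depth=3, ffn_layers=2, ffn_hidden_dim=64,
                    extra_route="route1_linear_relu", extra_placement="before_mpnn",
                    extra_embed_dim=64)
s1, _ = train(ds3.subset(split.train), ds3.subset(split.validation), coord, tcfg)
print("ts coord :", evaluate(s1, ds3.subset(split.test)).as_dict())
```

prints (a few minutes on one CPU):

```
no coord : {'mae': 1.772, 'rmse': 2.116, 'n': 100}
ts coord : {'mae': 0.376, 'rmse': 0.481, 'n': 100}
```

The graph-only model is pinned at the mean absolute deviation of the
uniform geometry term (γ·width/4 = 1.75 kcal/mol); the model that sees TS
coordinates through AEV features removes almost all of it and approaches
the 0.5 kcal/mol noise floor.  The same pipeline is scriptable from the
shell (`rxnbarrier generate / split / train / evaluate / importance /
predict`); real datasets enter as CSV reaction tables plus annotated XYZ
conformer files.

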