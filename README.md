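# lrcmc — Laplacian rank constrained multiview clustering

`lrcmc` clusters samples that are observed through several feature spaces at
once — the canonical case being cancer patients measured on multiple omics
layers (mRNA expression, DNA methylation, miRNA expression) — without a
separate k-means or spectral post-step. It is a one-step graph-learning
method: graph construction, graph fusion and clustering are solved jointly,
and the final labels are read directly off the learned graph.

## The model

For each view `v` with data `X^v ∈ R^{d_v×n}`, a column-stochastic affinity
graph `S^v` is learned by the *adaptive neighbors* rule: column `j` is a
probability distribution over the other samples, supported on its `k`
nearest candidates, obtained from a regularized simplex-constrained
quadratic problem (the per-column ridge strength is set implicitly so each
column has exactly `k` nonzeros — it is never a user parameter).

The views are fused into a consensus graph `Z` by minimizing

```
Σ_v [ 2 Tr(F^vᵀ L^v F^v) + α‖S^v‖_F² + w_v ‖Z − S^v‖_F² ]  +  2β Tr(Uᵀ L_Z U)
s.t.  F^vᵀF^v = I,  UᵀU = I,  columns of S^v and Z on the simplex, zero diagonal
```

where `L` denotes the symmetrized graph Laplacian, `F^v` and `U` are spectral
embeddings, and `w_v = 1/(2‖Z − S^v‖_F)` is the self-tuned inverse-distance
weight — views that agree with the consensus count for more. The last term is
the **Laplacian rank constraint**: since the number of zero eigenvalues of a
graph Laplacian equals the number of connected components, pushing the `c`
smallest eigenvalues of `L_Z` to zero (a Ky Fan trace minimization) forces
`rank(L_Z) = n − c`, i.e. `Z` falls apart into exactly `c` components — the
clusters. The strength `β` is adapted automatically: halved while `Z` has too
many components, doubled while it has too few.

All five block updates have closed forms (eigenvectors or simplex-projected
column updates), so the whole pipeline is deterministic.

## Worked example

```python
from lrcmc import BlobSpec, LRCMCConfig, evaluate, fit, make_multiview_blobs

views, truth = make_multiview_blobs(BlobSpec(seed=7))   # 90 samples, 3 views
labels, state = fit(views, LRCMCConfig(c=3, k=10))
print(evaluate(truth.labels, labels.labels))
```

Running `python examples/01_cluster_synthetic_multiomics.py` prints

```
converged        : True (in 2 iterations)
consensus blocks : 3 connected components
ACC / NMI / Purity: 1.0000 / 1.0000 / 1.0000
```

ACC is the fraction of samples correct under the best one-to-one matching of
clusters to classes (Hungarian assignment), NMI the mutual information of the
two partitions normalized by the geometric mean of their entropies, and
purity the average dominant-class fraction per cluster. The consensus graph
ended with exactly `c = 3` connected components, so the labels required no
extra clustering step. `examples/02_noisy_view_downweighting.py` shows the
fusion weights discounting a corrupted view, and `examples/03_files_and_cli.py`
the file round-trip; the same flows are available from a shell:

```bash
lrcmc simulate --spec spec.yaml --out data/
lrcmc fit --view data/view_0.csv --view data/view_1.csv \
          --clusters 3 --neighbors 10 --out results/
lrcmc eval --truth data/labels.tsv --pred results/labels.tsv
```

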