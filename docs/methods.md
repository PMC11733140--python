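# Methods

This note documents the models and procedures implemented in `chemxplain`,
the defaults that matter, the numerical choices, and what the synthetic
generator does and does not emulate.

## Data model

The working container is a `MoleculeTable`: an n×d numeric feature matrix,
a label vector, and a task kind. Classification is inferred when the label
values are exactly {0, 1}, overridable by configuration. Validation drops
rows rather than imputing — a surrogate fitted on imputed values attributes
importance to the imputation, not the chemistry — and every dropped row is
logged with a reason code (`missing_label`, `bad_feature_value`,
`invalid_smiles`) and emitted in a JSON-lines exclusion report.

SMILES inputs are featurized into the 167 public MACCS keys (RDKit),
binary answers to fixed structural yes/no questions; bit 0 is the
conventional unused placeholder. A packaged catalog maps each key to a
human-readable description (curated prose over the MDL shorthand codes);
unknown feature names fall back to the name itself, so description lookup
is total.

## Surrogate

XGBoost gradient-boosted trees with fixed hyperparameters
(100 estimators, depth 3, learning rate 0.1, no subsampling, λ = 1,
`hist`, single thread). Fixed rather than searched: the explanation
pipeline needs auditable, bit-reproducible fits more than the last decimal
of accuracy, and hyperparameter search would couple the attribution study
to a stochastic optimization. The holdout is 20%, stratified for
classification, split by the run's seed. Metrics: RMSE/R² (regression),
accuracy/F1 (classification), computed on the holdout only. Single-threaded
`hist` training is deterministic, which the suite asserts bitwise.

## Attributions

### Interventional tree Shapley values (exact)

For tree ensembles the package computes Shapley values of the
interventional value function v(S) = E_{z∈Z}[f(x_S, z_{S̄})] exactly. Per
leaf, the root path's split conditions are merged into per-feature
intervals; for an (x, z) pair each path feature is satisfied by both, by x
only (set A, |A| = a), by z only (set B, |B| = b), or by neither (leaf
unreachable under every coalition). The leaf's indicator is the game
1{A ⊆ S, B ∩ S = ∅}, whose Shapley values are
+v·(a−1)!·b!/(a+b)! for members of A and −v·a!·(b−1)!/(a+b)! for members of
B; all other features are null players. Summing over leaves and trees and
averaging over the background gives φ with no sampling error; the
efficiency identity Σ_j φ_ij + E_z[f(z)] = f(x_i) holds to float32 leaf
precision (the suite asserts 1e-6), and a brute-force subset-enumeration
oracle (d ≤ 12) verifies the closed form.

The background is the attributed dataset subsampled to 100 seeded rows.
For classification, attributions live in margin (log-odds) space — the only
space additive across trees — and the oracle uses the same margin-valued
prediction so both routes measure one quantity; the space is recorded in
the attribution metadata.

### LIME-style local surrogate

Each explained row is perturbed 1000 times (each feature independently
kept with probability 0.5 or redrawn from the training marginal); a ridge
regression (α = 1) of the model output on same-as-original indicators,
weighted by an RBF kernel of width 0.75·√d on the indicator
representation, yields per-feature local weights. At most 500 rows are
explained (the whole dataset when smaller). For classification the target
is the predicted probability.

### Globalization and direction calls

Shapley: G_j = mean_i |φ_ij|, ranked by G. LIME: s_j = mean_i |w_ij| is
standardized across features, z_j = (s_j − mean)/sd, G_j = max(z_j, 0),
ranked by z_j (all-equal scores degrade to z = 0 with a warning). Ranks
break ties lexicographically by feature name for determinism.

Directions use a relative dead-band δ = 0.01·max_j G_j. For LIME the
signed summary is the mean signed weight — local weights are slopes, so
their sign is the direction. For Shapley values the mean signed value is
approximately zero by construction on balanced features (rows with the
feature "on" are pushed one way, rows with it "off" the other), so the
signed summary is instead the covariance between feature value and
attribution, scaled by the feature's standard deviation — the criterion a
beeswarm plot encodes visually. |summary| ≤ δ is called "unclear".

Global Shapley aggregation attributes a seeded subsample of at most 500
rows — the same cap the LIME protocol uses — which estimates mean |φ|
without materially affecting rankings at the problem sizes studied.

## Retrieval

Corpora are directories of plain-text/markdown files (no PDF extractor is
bundled; PDFs are skipped with a warning). Documents are chunked by a
sliding window (1000 characters, 200 overlap, preferring a whitespace cut
within 50 characters); the next window starts exactly `overlap` characters
before the previous cut, so consecutive chunks overlap by exactly the
configured amount except at the document end, and stripping overlaps by
span reconstructs the document byte-exactly.

The embedder is a deterministic hashed TF-IDF vectorizer: lowercase
alphanumeric tokens, md5-hashed into 2048 buckets, smoothed-IDF weighted,
L2-normalized. 2048 buckets keep the collision floor between disjoint
vocabularies near cosine 0.05 on short chunks. It runs offline with no
keys or network; remote embedding services fit behind the same
fit/transform contract.

Excerpt selection is greedy maximal marginal relevance with λ = 0.5 and
k = 4 excerpts per feature; at λ = 1 the selection reduces exactly to a
similarity sort, and the implementation is tested against a step-by-step
brute-force greedy oracle. Ties resolve to the lowest candidate index. The
per-feature query is the humanized description plus the target property
name; when the best similarity is below 0.1 — indistinguishable from the
hashing collision floor — the result is flagged low-confidence.

## Generation and citations

The prompt is a versioned template (preamble, per-feature evidence blocks
with `[SOURCE doc:chunk]` tags, chain-of-thought instructions with a worked
example). Rendering is deterministic; a feature without retrieved evidence
is kept with a `NO_EVIDENCE` marker. Backends implement
`generate(prompt, seed) -> text`; runs use consecutive seeds and failures
are retained as failed-run records, never dropped silently.

The mock backend is first-class, not a test shim: it scans each feature's
excerpts in MMR order and lets the first excerpt with a keyword majority
decide the direction ("increase/enhance/…" vs "decrease/reduce/…"),
citing that excerpt; pooled voting across all excerpts was rejected because
off-topic excerpts sharing only the property word could outvote the
feature-specific document on small corpora. Without keyword evidence it
emits the verbatim disclaimer "an explicit relationship was not found in
the given documents" and no citation. Free-text outputs from other
backends are parsed by a declared rule: `DIRECTION:` tags when present,
else a direction-keyword scan of the sentence containing the feature
description, else unclear.

Citation markers are resolved against the corpus registry; resolvable
markers render as "(FirstSourceToken, Year|n.d.)", unresolvable ones
become "[unresolved]" and are counted. A hypothesis is "supported" only
while it retains at least one resolvable citation, so no explanation can
cite a document outside the ingested corpus — the anti-hallucination
guarantee is structural.

## Evaluation

Hypothesis precision over repeated runs:
precision = (1/(N_features·N_runs)) Σ_i |n_{i,pos} − n_{i,neg}|, with
features absent from a run counted as unclear so each feature's counts sum
to N_runs and the denominator is well-defined. The score is bounded in
[0, 1], invariant to feature/run permutation, and monotone as directional
labels degrade to unclear.

ROUGE-L uses whitespace tokens, a dynamic-programming LCS (verified against
the exponential recursive oracle), and the F1 (β = 1) convention
R = LCS/|ref|, P = LCS/|cand|, F = 2RP/(R+P); variability is the mean ± sd
of F over all unordered run pairs.

The citation audit is substring-level by design: a citation is *supported*
iff the cited chunk contains the feature description, name, or catalog
synonym (case-insensitive). Semantic entailment is out of scope; the audit
measures grounding, not correctness.

## Synthetic generator

Features are i.i.d. Bernoulli(0.5); a sparse support S carries signed
weights w. Regression labels are Σ_{j∈S} w_j x_ij + N(0, σ²);
classification draws Bernoulli(logistic(Σ w_j x_ij + b)) with b centering
the linear term so prevalence is ≈0.5 — balanced classes keep
attribution-recovery results unconfounded by base rates. The companion
corpus generator writes one short document per directional claim
("… increases/decreases <property> …") plus off-topic filler.

The generator emulates what the attribution study needs — a known sparse
ground truth with controllable noise — and deliberately not what real
molecular data looks like: features are independent (no fingerprint bit
correlations), effects are additive (no interactions or saturation), and
the corpus asserts claims in regular, keyword-bearing sentences. Passing
the recovery and precision suites therefore demonstrates correctness of
the machinery under known ground truth, not performance on correlated
descriptors or adversarial literature.

The reference study conditions for support recovery are n = 2000, d = 20,
|S| = 3, |w| = 1.5 with mixed signs, σ = 0.1, 20 replicate seeds; unit
tests use smaller tables (n = 60–500) chosen to keep the default suite
fast while exercising the same code paths.

## Determinism

One master seed is fanned out via `numpy.random.SeedSequence` to the
split, SHAP background, LIME sampling, and generation stages. With the
mock backend a rerun of the same configuration reproduces every artifact
hash; the manifest records per-artifact SHA-256, stage timings, versions,
and the (fixed) surrogate hyperparameters.

## Known limitations

- Exact interventional Shapley cost grows as
  O(trees · leaves · path · n · |Z|); it is comfortable at the studied
  sizes but not at thousands of deep trees with large backgrounds.
- The hashed embedder has no semantics: synonyms of a feature description
  do not retrieve unless they share tokens. Feature descriptions should be
  phrased the way the corpus phrases them.
- The mock backend's direction extraction is keyword-based and
  English-only; negation ("does not increase") is not modeled.
- The LIME z-score standardization is across features (not across
  instances per feature); both produce rankings, and the cross-feature
  form is the one implemented and documented.
- arXiv scraping is an unimplemented stub; corpora are local directories.
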