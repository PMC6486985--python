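# dxcover

Differential diagnosis by weighted set covering over a computable
symptom–disease knowledge base.

Diagnostic decision-support prototypes need a knowledge base that a machine
can actually compute over: not just a vocabulary of diseases and symptoms,
but quantified links between them.  `dxcover` provides such a substrate and a
reference inference engine on top of it, aimed at medical-informatics
researchers and students prototyping diagnostic assistants.

## The model

The knowledge base is a weighted bipartite relation between **explanations**
(ICD-10-style diseases, RxNorm-style medication side effects) and
**findings** (SNOMED/LOINC-style signs, symptoms, lab results).  Each
association carries a weight

> *w(s, d) ∈ [0, 1]* — the conditional frequency of finding *s* given
> explanation *d* (an always-present finding weighs 1.0, one seen in 10% of
> cases weighs 0.1); the special value **−1** marks a *negating* finding that
> rules the explanation out.

Explanations also carry binary geographic priors (region tags), broad age
groups (infant / child / adult / elderly) and sex constraints, all of which
act as hard eligibility filters on a query.

Given observed findings *S*, diagnosis is cast as **weighted set covering**:
find a small set *D* of eligible explanations maximizing the symptom cover
weight

```
m(D) = Σ_{s ∈ S}  max(0, max_{d ∈ D} w(s, d))
```

*m* is monotone and submodular, so the greedy algorithm that repeatedly adds
the explanation with the largest marginal gain *m(D ∪ {d}) − m(D)* enjoys
the classical (1 − 1/e) approximation guarantee; a brute-force oracle is
included for small instances.  For single-explanation differentials, each
candidate is scored additively (Σ of positive weights over observed
findings) and the top *k* (default 20) are returned with tie groups.  A
naive-Bayes mode is also available.

Benchmarking follows a rank-bucket protocol: the rank of the correct
diagnosis maps to nested Top-1 / Top-10 / Top-20 buckets and a utility score
(Top1 → 3, Top10 → 2, Top20 → 1, miss → 0); tools are compared by Top-n
percentages, mean utility, and paired Wilcoxon signed-rank tests (exact null
distribution up to n = 25, tie-corrected normal approximation beyond).

A synthetic-data module generates knowledge bases with the realistic shape
of a curated KB (~2000 explanations, ~8000 findings, long-tailed
findings-per-disease distribution: ~14% single-finding, ~42% with ≤5, ~28%
with ≥10, tail to 67) plus labeled patient cases, so the whole pipeline runs
without any external data.

## Worked example

The repository ships a four-finding toy knowledge base under
`tests/data/toy_kb/`.  Querying it for a febrile patient with headache:

```
$ dxcover query --kb tests/data/toy_kb --finding Fever --finding Headache
# single mode, k=20
rank    explanation_id  label       score   n_matched  tie_group
1       E001            Malaria     1.7500  2          0
2       E002            Influenza   0.7500  2          1
3       E003            Drug fever  0.3000  1          2
```

Malaria leads with score 1.75 = w(fever, malaria) + w(headache, malaria)
= 1.0 + 0.75; each score is the sum of the case's observed-finding weights
for that explanation, so it grows with the number of related observations.
Geography is a hard filter — malaria is tagged with Africa and SouthAmerica
presence only, so restricting the patient's region removes it entirely:

```
$ dxcover query --kb tests/data/toy_kb --finding Fever --region NorthAmerica
# single mode, k=20, regions=NorthAmerica
rank    explanation_id  label       score   n_matched  tie_group
1       E002            Influenza   0.5000  1          0
2       E003            Drug fever  0.3000  1          1

$ dxcover query --kb tests/data/toy_kb --finding Fever --region Africa
# single mode, k=20, regions=Africa
rank    explanation_id  label       score   n_matched  tie_group
1       E001            Malaria     1.0000  1          0
2       E002            Influenza   0.5000  1          1
3       E003            Drug fever  0.3000  1          2
```

Because the toy KB encodes rash as negating for malaria (weight −1), adding
`--finding Rash` to a query excludes malaria outright.  `dxcover stats`
prints the shape summary (here: 3 explanations, 100% with ≤5 findings, 33%
single-finding; most-referenced finding "Fever" with 3 links), `dxcover gen`
writes a synthetic KB + cases + ground truth, `dxcover validate` checks every
invariant, and `dxcover eval` turns a records table into the Top-n/utility
summary with pairwise signed-rank tests.

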