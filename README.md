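# summdiv

Diversity-based personalization metrics for clinical summaries of
social-media timelines.

## The problem

When clinicians or language models summarize a user's timeline of posts, a
key quality dimension is *personalization*: does each summary reflect that
user's idiosyncratic content, or does the summarizer emit near-identical
generic text for everyone? Gold references rarely exist for this judgement,
but personalization leaves a measurable footprint: a templated system's
summaries resemble *each other*. `summdiv` quantifies that footprint as
within-system diversity and tests whether systems (e.g. human experts vs LLM
pipelines) differ significantly. It is aimed at researchers evaluating
timeline summarization systems — in computational mental health or any
domain with one summary per (unit, system) pair.

## The statistics

**Self-ROUGE** (surface diversity). For a system with summaries
s₁…s_m, and a ROUGE variant R:

```
self-ROUGE = (2 / m(m−1)) · Σ_{i<j} R_F(sᵢ, sⱼ)
```

the mean pairwise ROUGE F₁ over all within-system pairs; lower = more
lexically diverse. Six variants: ROUGE-1/2/3 (clipped n-gram overlap),
ROUGE-L (longest common subsequence), ROUGE-S2 (skip-bigrams with ≤ 2
intervening words) and ROUGE-SU2 (skip-bigrams ∪ unigrams).

**Semantic diversity.** Embed each summary, unit-normalize, take the
centroid **c** = mean(vᵢ), and report mean_i cos(vᵢ, **c**); lower = more
semantically diverse. Embedders are pluggable; a deterministic hashed
bag-of-words `reference` embedder is bundled, and sentence-transformer
models can be registered behind the same contract.

**Inference.** Systems are compared with a paired permutation test: each
timeline's two summaries are label-swapped with probability ½, B = 1000
permutations, two-sided p with add-one smoothing (an exhaustive 2ⁿ mode
exists for n ≤ 20). Effect sizes are Cohen d over per-summary scores. The
same machinery compares 1–5 Likert ratings tables (raters averaged within
timeline first).

**Synthetic corpora.** Because real clinical summary sets are typically
restricted, a bundled generator produces paired-complete multi-system
corpora with controllable diversity dials (template pool size, synonym
substitution rate, timeline-specific token rate) and synthetic ratings with
target means — making every stage of the pipeline testable end to end.

## Worked example

```bash
summdiv simulate --seed 7 --timelines 30 --out-dir demo   # synthetic 4-system corpus
summdiv surface  --corpus demo/corpus.jsonl --out demo/surface.csv
summdiv semantic --corpus demo/corpus.jsonl --out demo/semantic.csv
summdiv report   --surface demo/surface.csv --semantic demo/semantic.csv --out demo/report.csv
```

`demo/report.csv` (metric × system grid; lower = more diverse):

```
            metric  human  llama  naive-llama  th-vae
            rouge1   0.31   0.49         0.40    0.49
            rouge2   0.08   0.28         0.14    0.27
            rouge3   0.03   0.20         0.07    0.19
            rougeL   0.20   0.36         0.26    0.36
           rougeS2   0.07   0.26         0.13    0.25
          rougeSU2   0.13   0.32         0.20    0.31
semantic:reference   0.80   0.89         0.84    0.88
           Average   0.23   0.40         0.29    0.40
```

The synthetic "human" profile (full template pool, heavy synonym use,
frequent personal content) is the most diverse on every metric — lowest
self-ROUGE and lowest centroid similarity — the naive baseline is
intermediate, and the two templated model profiles are the least diverse.

```bash
summdiv compare --corpus demo/corpus.jsonl --metrics rouge-1 --seed 7 --out demo/cmp.csv
```

```
                pair             metric  value_a  value_b  p_value  cohen_d
      human vs llama  self_rouge:rouge1    0.314    0.491    0.001   -8.261
      human vs llama semantic:reference    0.796    0.885    0.001   -2.746
human vs naive-llama  self_rouge:rouge1    0.314    0.398    0.001   -3.599
human vs naive-llama semantic:reference    0.796    0.844    0.002   -1.234
     human vs th-vae  self_rouge:rouge1    0.314    0.491    0.001   -6.638
     human vs th-vae semantic:reference    0.796    0.883    0.001   -2.616
```

Each row: the two systems' diversity values, the paired permutation p-value
(B = 1000; 0.001 is the smallest attainable) and Cohen d over per-summary
scores — negative d means system A (human) scores *lower*, i.e. is more
diverse. With these generator settings every human-vs-model difference is
significant at p ≤ 0.002 with large effects.

The same objects are available as a library:

```python
from summdiv import generate_corpus, self_rouge, semantic_diversity
from summdiv.synthetic import CorpusSpec, default_study_profiles

corpus = generate_corpus(CorpusSpec(profiles=default_study_profiles(), seed=7))
print(self_rouge(corpus, "human", "rouge1").value)        # 0.314...
print(semantic_diversity(corpus, "human").value)          # 0.796...
```

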