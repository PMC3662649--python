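"""Train a K-TSP classifier on a simulated discovery cohort and validate it.

Simulates a 70-gene cohort with eight planted switching pairs of tapering
strength, trains under the 100%-training-sensitivity constraint with the
K = 6..10 search window, then evaluates on an independent cohort from the
same process.
"""

from ktsp import (
    confusion_metrics,
    evaluate_predictions,
    generate_cohort,
    predict,
    select_k_and_threshold,
)

planted = [(i, 0.95 - 0.05 * i, 0.05 + 0.05 * i) for i in range(8)]

train = generate_cohort(n_genes=70, n_poor=34, n_good=44,
                        planted=planted, seed=11)
model = select_k_and_threshold(train, k_range=(6, 10))
print(f"selected K = {model.k}, vote threshold = {model.threshold}")
for i, p in enumerate(model.pairs, 1):
    print(f"  pair {i}: {p.gene_a} vs {p.gene_b} "
          f"(delta={p.delta:.3f}, votes poor when "
          f"{p.gene_a} {'<' if p.orientation == 'lt' else '>'} {p.gene_b})")

calls = predict(train, model)
sens, spec, acc = confusion_metrics(calls["label"].to_numpy(), train.labels)
print(f"training (resubstitution): sens={sens:.2f} spec={spec:.2f} acc={acc:.2f}")

val = generate_cohort(n_genes=70, n_poor=153, n_good=154,
                      planted=planted, seed=12)
calls = predict(val, model)
report = evaluate_predictions(
    scores=calls["score"].to_numpy(),
    predicted=calls["label"].to_numpy(),
    truth=val.labels,
    n_boot=2000,
    seed=13,
)
print()
print(report.to_text())
print()
print("Sensitivity/specificity are the fractions of poor/good-prognosis")
print("samples called correctly; the AUC is the probability a random poor")
print("sample out-scores a random good one (ties count one half).")
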