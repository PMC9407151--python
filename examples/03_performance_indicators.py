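"""Performance indicators: learning curve and ROC.

Trains on progressively larger annotation subsets to show precision
climbing to its maximum of 1, then sweeps the ROC of one defect class'
probability plane against the annotated truth — on a separable fixture it
matches the ideal classifier (AUC = 1).
"""

import frfseg

total = 160 * 256
params = frfseg.SceneParams(
    height=160, width=256,
    classes=(
        frfseg.DefectClassSpec(
            name="defect", mean=0.35, sd=0.05, correlation_length=4.0,
            orientation_deg=30.0, blob_areas_px=(round(0.06 * total),),
        ),
    ),
)
scene = frfseg.generate_scene(params, seed=2)
labels = frfseg.sample_labels(scene, n_per_class=100, seed=3)
stack = frfseg.build_stack(scene.image)

curve = frfseg.learning_curve(stack, labels, schedule=[5, 20, 50, 100, 200],
                              n_trees=50, seed=4)
print("instances  precision  recall")
for n, p, r in zip(curve.instances, curve.precision, curve.recall):
    print(f"{n:>9}  {p:>9.3f}  {r:>6.3f}")

model = frfseg.train(stack, labels, n_trees=50, seed=4)
_, prob = frfseg.predict(model, stack)
roc = frfseg.roc(prob, labels, positive_class="defect")
print(f"ROC AUC(defect) = {roc.auc:.3f}")
# Precision is evaluated on the training annotations themselves (the
# protocol trains and tests on the same image); AUC 1.0 means some
# threshold separates annotated defect from background pixels perfectly.
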