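"""Same-image training, classification and defect quantification.

Runs the core protocol on a synthetic scene: build the default feature
bank (Gaussian + Hessian family + membrane projections, sigma 1..16),
train the random forest on the sparse labels, classify every pixel,
threshold each defect class's probability plane at 0.5 and report
coverage in percent and mm^2 next to the known truth.
"""

import frfseg

total = 160 * 320
params = frfseg.SceneParams(
    height=160, width=320,
    classes=(
        frfseg.DefectClassSpec(
            name="C1", mean=0.35, sd=0.05, correlation_length=4.0,
            orientation_deg=30.0, blob_areas_px=(round(0.053 * total),),
        ),
        frfseg.DefectClassSpec(
            name="C2", mean=0.55, sd=0.05, correlation_length=8.0,
            orientation_deg=120.0, blob_areas_px=(round(0.041 * total),),
        ),
    ),
)
scene = frfseg.generate_scene(params, seed=11)
labels = frfseg.sample_labels(scene, n_per_class=80, seed=5)

stack = frfseg.build_stack(scene.image)
print(f"feature stack: {stack.n_features} planes")

model = frfseg.train(stack, labels, n_trees=100, seed=3)
metrics = frfseg.evaluate(model, stack, labels)
print(f"training precision = {metrics['micro_precision']:.3f}, "
      f"recall = {metrics['micro_recall']:.3f}")

class_map, prob = frfseg.predict(model, stack)
report = frfseg.quantify(prob, scene.image, skip_classes=("background",))
print(report.format_table())
truth = scene.coverage_percent()
for entry in report.entries:
    print(f"  {entry.class_name}: measured {entry.coverage_percent:.2f} % "
          f"vs truth {truth[entry.class_name]:.2f} %")
# Measured coverage should sit within about one percentage point of truth:
# the textures are separated by >4 standard deviations, so the forest's
# 0.5-thresholded probability maps recover the constructed blobs.
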