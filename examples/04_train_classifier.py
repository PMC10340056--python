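"""Train the shuffle/attention extractor + CRNN head on easy synthetic data.

A small model on a well-separated 5-class set: per-epoch training and
validation error should fall from the 80% chance level toward zero within
a dozen epochs.
"""

from histotune import (
    CRNNConfig,
    ExtractorConfig,
    ImageClassifier,
    SyntheticSpec,
    TrainConfig,
    generate_dataset,
    prepare_images,
    split_dataset,
    train_classifier,
)

dataset = generate_dataset(
    SyntheticSpec(images_per_class=40, image_size=16, difficulty=0.1, seed=3)
)
train, test = split_dataset(dataset, 0.8, seed=3)

model = ImageClassifier(
    ExtractorConfig(stage_widths=(4, 8), input_size=16),
    CRNNConfig(conv_widths=(8,), lstm_units=16),
    seed=0,
)
history = train_classifier(
    model,
    (prepare_images(train.images), train.labels),
    (prepare_images(test.images), test.labels),
    TrainConfig(epochs=12, learning_rate=3e-3, seed=0),
)
for e, (tl, te, ve) in enumerate(zip(history["train_loss"], history["train_error"],
                                     history["val_error"]), 1):
    print(f"epoch {e:2d}: train loss {tl:.3f}  train err {te:5.1f}%  val err {ve:5.1f}%")
# The error columns are misclassification percentages (chance = 80% for 5
# balanced classes); a steadily falling validation error shows the model is
# learning stain/texture signal rather than memorizing.
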