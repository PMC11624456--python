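# Sex indicator terms -> canonical sex category.
man	male
men	male
male	male
males	male
boy	male
boys	male
woman	female
women	female
female	female
females	female
girl	female
girls	female
lady	female
ladies	female
trans	transgender
transgender	transgender
transgender individuals	transgender
transgender people	transgender
trans people	transgender
transgender man	transgender man
transgender men	transgender man
trans man	transgender man
trans men	transgender man
transgender woman	transgender woman
transgender women	transgender woman
trans woman	transgender woman
trans women	transgender woman
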