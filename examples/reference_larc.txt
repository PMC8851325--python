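Long-acting reversible contraceptives include the intrauterine device and
the contraceptive implant. An IUD is a small device placed in the uterus by
a clinician; hormonal and copper versions are available. The contraceptive
implant is a thin rod inserted under the skin of the upper arm. The
contraceptive shot, such as Depo Provera, is an injection given every three
months. All of these methods are highly effective, reversible, and require
a visit with a health care provider. Students can ask the student health
center about insertion, removal, side effects, and insurance coverage.
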