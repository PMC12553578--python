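# Default exclusion list: 13 common domestic mammal species (binomials).
# This is an editable stand-in; swap in your own list via configuration.
Felis catus
Canis familiaris
Bos taurus
Equus caballus
Equus asinus
Sus domesticus
Ovis aries
Capra hircus
Lama glama
Vicugna pacos
Camelus dromedarius
Bubalus bubalis
Oryctolagus cuniculus
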