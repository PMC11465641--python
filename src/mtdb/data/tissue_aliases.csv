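alias,tissue
egg,whole_egg
eggs,whole_egg
whole egg,whole_egg
whole-egg,whole_egg
egg content,whole_egg
egg contents,whole_egg
yolk,yolk
egg yolk,yolk
albumen,albumen
egg white,albumen
follicle,follicle
follicles,follicle
ovarian follicle,follicle
hatchling blood,hatchling_blood
blood,whole_blood
whole blood,whole_blood
adipose,fat
adipose tissue,fat
abdominal fat,fat
fat body,fat
blood plasma,plasma
serum,plasma
gall bladder,bile
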