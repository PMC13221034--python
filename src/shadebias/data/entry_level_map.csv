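subcategory_label,entry_category
bathtub,bathtub
tub,bathtub
koala,bear
brown bear,bear
black bear,bear
polar bear,bear
sloth bear,bear
red panda,bear
giant panda,bear
house finch,bird
snowbird,bird
indigo finch,bird
robin,bird
bulbul,bird
jay,bird
magpie,bird
chickadee,bird
water ouzel,bird
ringlet butterfly,butterfly
monarch butterfly,butterfly
cabbage butterfly,butterfly
sulphur butterfly,butterfly
lycaenid butterfly,butterfly
indian elephant,elephant
african elephant,elephant
goldfish,fish
crampfish,fish
devilfish,fish
eel,fish
coho,fish
rock beauty,fish
anemone fish,fish
sturgeon,fish
garfish,fish
lionfish,fish
pufferfish,fish
crash helmet,helmet
football helmet,helmet
gasmask,helmet
mailbox,mailbox
coffee mug,mug
cellular telephone,phone
dial telephone,phone
payphone,phone
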