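# Default firearm taxonomy: 27 phrases deemed clinically relevant.
# One phrase per line; matching is case-insensitive on alphanumeric tokens.
rifle
pistol
shotgun
12 gauge
9 mm glock
45 caliber
22 caliber
semiautomatic
357 magnum
m1 rifle
gun
guns
firearm
firearms
38 caliber
9 mm beretta
arms dealer
blue suicide
home invasion
minigun
mossberg shotgun
pistol whip
revolver
ruger pistol
smith and wesson
sniper rifle
winchester rifle
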