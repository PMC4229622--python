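# acinar rule table, one rule per line (ids = line order)
Bile = Bile
!Ca + Bile = Ca
PMCh = Ca
2 !ATP = Ca
2 Ca = Ca
!Ca + !CaMem + 2 Bile = 2 Ca
Ca = CaMem
2 Ca = 2 CaMem
2 Ca = PMCh
2 !ROS = NADH
2 NADH = NADH
NADH + 2 Ca = 2 NADH
2 !Pores = Pot
2 Pot = Pot
Pot + 2 NADH + 2 !Pores = 2 Pot
!Pot = ATP
2 ATP = ATP
ATP + Pot = 2 ATP
Pot = ROS
2 ROS = ROS
ROS + 2 Pot + 2 !AntiOx = 2 ROS
ROS + Pot + Ca + 2 !AntiOx = 2 ROS
ROS + CytC + 2 !AntiOx = 2 ROS
3 ROS = 2 ROS
2 ROS + Ca + CytC + !AntiOx = 3 ROS
2 !Ca = AntiOx
2 !Pores = AntiOx
2 AntiOx = AntiOx
AntiOx + 2 NADH + !Ca + 2 !Pores = 2 AntiOx
Ca = Pores
2 ROS = Pores
2 Pores = Pores
Pores + Ca + CaMem = 2 Pores
2 ROS = CytC
2 CytC = CytC
CytC + 3 ROS = 2 CytC
ATP + CytC + Pores = Apt
ATP + 2 CytC + Pores = 2 Apt
Ca + CaMem = Necr
2 Ca + !(ATP + 2 CytC + Pores) = 2 Necr
Ca + CaMem + !(ATP + 2 CytC + Pores) = 2 Necr
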